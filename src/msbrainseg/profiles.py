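"""Bundled experiment profiles.

``reference_profile`` is the full-scale setup: 512 px slices, 65 px windows,
the 2,856,932-parameter network, 150/325 window sampling and the 80-epoch
schedule.  Training it is a multi-day job on this kind of pixel-wise
sliding-window architecture, so the package also ships ``desk_profile``, a
scaled-down configuration (128 px phantoms, 13 px windows, [16, 12, 8]-map
pathways, 20/45 sampling, 10 epochs) whose 5-fold cross-validation finishes
in a couple of minutes on one CPU while exercising every pipeline stage.
The desk profile shortens the schedule, so it compensates with a smaller
batch (more SGD steps), a doubled learning rate and lighter dropout; see
docs/methods.md for the reasoning.
"""

from __future__ import annotations

from dataclasses import dataclass

from .augment import ElasticParams
from .network import NetworkConfig
from .phantom import PhantomConfig
from .train import TrainConfig

__all__ = ["Profile", "reference_profile", "desk_profile"]


@dataclass(frozen=True)
class Profile:
    phantom: PhantomConfig
    network: NetworkConfig
    train: TrainConfig
    elastic: ElasticParams
    stride: int
    tau_c: float


def reference_profile(seed: int = 0) -> Profile:
    """Full-scale configuration (matches the published setup)."""
    return Profile(
        phantom=PhantomConfig(image_size=512, n_per_class=20, seed=seed),
        network=NetworkConfig(),
        train=TrainConfig(seed=seed),
        elastic=ElasticParams(alpha=51.2, sigma=10.24, seed=seed),
        stride=1,
        tau_c=0.75,
    )


def desk_profile(seed: int = 0, n_per_class: int = 20) -> Profile:
    """Scaled-down configuration for single-CPU end-to-end runs."""
    return Profile(
        phantom=PhantomConfig(image_size=128, n_per_class=n_per_class, seed=seed),
        network=NetworkConfig(
            window_size=13,
            pathway_kernels=(5, 3, 3),
            pathway_maps=(16, 12, 8),
            concat_maps=24,
            dropout_rate=0.25,
        ),
        train=TrainConfig(
            epochs=10, lr0=0.01, batch_size=64, seed=seed, n_pos=20, n_neg=45
        ),
        elastic=ElasticParams(alpha=12.8, sigma=2.56, seed=seed),
        stride=8,
        tau_c=0.0,
    )
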