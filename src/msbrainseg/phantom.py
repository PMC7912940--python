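"""Synthetic brain-slice phantoms.

Each phantom emulates one record of a contrast-enhanced axial/coronal MRI
slice dataset: a dark scanner background, a bright skull ring (deliberately
NOT stripped), a smooth brain interior, a bright sinus-like midline structure,
and exactly one lesion whose texture depends on the tumor class:

* class 1 (meningioma analogue) — bright, homogeneous, attached to the skull;
* class 2 (glioma analogue)     — heterogeneous, high local variance, deep in
  the parenchyma;
* class 3 (pituitary analogue)  — compact, near the inferior midline next to
  the sinus-like structure, a known confusion source.

Records carry the same fields as the real dataset: grayscale image, class
label, binary tumor mask, ordered tumor-border polyline, and a patient id.
Intensities are floats in [0, 1]; the arbitrary scale of real data is removed
downstream by standardization. All geometry is parameterized relative to
``image_size`` so the same configuration scales from desk-size tests to
full-resolution runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .exceptions import GenerationError, ValidationError

__all__ = [
    "TextureParams",
    "PhantomConfig",
    "SliceRecord",
    "trace_boundary",
    "generate_phantom",
    "generate_dataset",
]


@dataclass(frozen=True)
class TextureParams:
    """Statistical description of a lesion texture.

    base
        Mean lesion intensity on the [0, 1] scale.
    contrast
        Amplitude of the smooth texture component (standard deviations of
    intensity around ``base``).
    frequency
        Spatial frequency of the texture in cycles per 256 px; higher values
        give finer granularity.
    homogeneity
        In [0, 1]; 1 means purely smooth texture, lower values add white
        speckle of amplitude ``(1 - homogeneity) * contrast``.
    """

    base: float
    contrast: float
    frequency: float
    homogeneity: float


def _default_textures() -> dict[int, TextureParams]:
    return {
        1: TextureParams(base=0.80, contrast=0.05, frequency=10.0, homogeneity=0.90),
        2: TextureParams(base=0.52, contrast=0.20, frequency=45.0, homogeneity=0.35),
        3: TextureParams(base=0.70, contrast=0.10, frequency=22.0, homogeneity=0.75),
    }


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings; defaults are the package's reference conditions."""

    image_size: int = 256
    n_per_class: int = 10
    seed: int = 0
    lesion_radius_range: tuple[float, float] = (0.055, 0.09)  # fraction of image_size
    noise_sd: float = 0.02
    slices_per_patient: int = 2
    class_texture_params: dict[int, TextureParams] = field(
        default_factory=_default_textures
    )

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValidationError("image_size must be at least 32 px")
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi < 0.5):
            raise ValidationError("lesion_radius_range must satisfy 0 < lo <= hi < 0.5")
        if self.slices_per_patient < 1:
            raise ValidationError("slices_per_patient must be >= 1")


@dataclass
class SliceRecord:
    """One dataset item: image, tumor class, mask, border polyline, patient id.

    ``label`` is the ground-truth tumor type l_gt in {1, 2, 3}; ``mask`` is the
    binary tumor mask T_ij; ``border`` is an ordered (n, 2) array of 0-based
    (row, col) boundary pixels lying on mask foreground.
    """

    pid: str
    label: int
    image: np.ndarray
    mask: np.ndarray
    border: np.ndarray

    def validate(self) -> "SliceRecord":
        if self.label not in (1, 2, 3):
            raise ValidationError(f"label must be in {{1,2,3}}, got {self.label}")
        if self.image.ndim != 2:
            raise ValidationError("image must be 2-D")
        if self.mask.shape != self.image.shape:
            raise ValidationError(
                f"mask shape {self.mask.shape} != image shape {self.image.shape}"
            )
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("mask values must be in {0,1}")
        if not (self.mask == 1).any():
            raise ValidationError("mask has no foreground pixels (tumor slices must contain tumor)")
        border = np.asarray(self.border)
        if border.ndim != 2 or border.shape[1] != 2:
            raise ValidationError("border must be an (n, 2) coordinate array")
        h, w = self.image.shape
        if (border < 0).any() or (border[:, 0] >= h).any() or (border[:, 1] >= w).any():
            raise ValidationError("border coordinates outside image bounds")
        if not self.mask[border[:, 0], border[:, 1]].all():
            raise ValidationError("border coordinates must lie on mask foreground")
        return self


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered boundary of a binary mask.

    A foreground pixel is a boundary pixel when at least one of its eight
    neighbors (or an out-of-bounds position) is background.  Pixels are
    returned ordered by angle around the foreground centroid, which yields a
    closed polyline for the star-convex lesions this package generates.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValidationError("cannot trace the boundary of an empty mask")
    interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    boundary = mask & ~interior
    rr, cc = np.nonzero(boundary)
    cen_r, cen_c = ndimage.center_of_mass(mask)
    order = np.argsort(np.arctan2(rr - cen_r, cc - cen_c), kind="stable")
    return np.stack([rr[order], cc[order]], axis=1).astype(np.int64)


def _ellipse_mask(shape, center, semi_axes):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / semi_axes[0]) ** 2 + (
        (cc - center[1]) / semi_axes[1]
    ) ** 2 <= 1.0


def _smooth_noise(rng, shape, sigma):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _lesion_center(rng, label, cfg, brain_axes, head_center, radius, sinus_center, sinus_r):
    s = cfg.image_size
    ar, ac = brain_axes
    margin = radius + 2.0
    if margin >= min(ar, ac):
        raise GenerationError(
            f"lesion radius {radius:.1f}px cannot fit inside brain ellipse "
            f"(semi-axes {ar:.1f}/{ac:.1f}px) at image_size {s}"
        )
    if label == 1:
        # against the inner skull edge
        theta = rng.uniform(0, 2 * np.pi)
        fr = 1.0 - margin / ar
        fc = 1.0 - margin / ac
        return (
            head_center[0] + ar * fr * np.sin(theta),
            head_center[1] + ac * fc * np.cos(theta),
        )
    if label == 2:
        # deep parenchyma, upper half to stay clear of the sinus region
        theta = rng.uniform(np.pi * 0.75, np.pi * 2.25)  # sin(theta) mostly <= 0
        rho = rng.uniform(0.0, 0.45)
        return (
            head_center[0] + ar * rho * np.sin(theta) - 0.08 * s,
            head_center[1] + ac * rho * np.cos(theta),
        )
    # label == 3: just superior to the sinus-like structure, near the midline
    gap = radius + sinus_r + 2.0
    return (
        sinus_center[0] - gap,
        sinus_center[1] + rng.uniform(-0.03, 0.03) * s,
    )


def generate_phantom(
    config: PhantomConfig, class_label: int, slice_seed: int, pid: str | None = None
) -> SliceRecord:
    """Generate one phantom slice of the requested tumor class.

    Deterministic: identical ``(config, class_label, slice_seed)`` yield
    bit-identical records.  Raises :class:`GenerationError` when the drawn
    lesion cannot be placed inside the brain ellipse.
    """
    if class_label not in (1, 2, 3):
        raise ValidationError(f"class_label must be in {{1,2,3}}, got {class_label}")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(class_label), int(slice_seed)])
    )
    s = config.image_size
    shape = (s, s)
    head_center = (0.5 * s, 0.5 * s)
    head_axes = (0.42 * s, 0.36 * s)  # rows taller than columns
    skull_outer = _ellipse_mask(shape, head_center, head_axes)
    skull_inner = _ellipse_mask(shape, head_center, (0.92 * head_axes[0], 0.92 * head_axes[1]))
    brain_axes = (0.93 * head_axes[0], 0.93 * head_axes[1])
    brain = _ellipse_mask(shape, head_center, brain_axes)

    image = np.full(shape, 0.02, dtype=np.float64)
    # brain parenchyma: mid gray with slow spatial variation
    parenchyma = 0.40 + 0.05 * _smooth_noise(rng, shape, sigma=0.08 * s)
    image[brain] = parenchyma[brain]
    # skull ring
    ring = skull_outer & ~skull_inner
    image[ring] = 0.88 + 0.03 * _smooth_noise(rng, shape, sigma=0.02 * s)[ring]
    # bright sinus-like structure on the inferior midline (present in every
    # slice; it is anatomy, not a class marker)
    sinus_center = (head_center[0] + 0.58 * brain_axes[0], head_center[1])
    sinus_r = 0.035 * s
    sinus = _ellipse_mask(shape, sinus_center, (sinus_r, 1.3 * sinus_r)) & brain
    image[sinus] = 0.82

    lo, hi = config.lesion_radius_range
    radius = rng.uniform(lo * s, hi * s)
    axis_ratio = rng.uniform(0.8, 1.0)
    lesion = None
    for _ in range(20):  # center draws are random; retry if the edge is grazed
        center = _lesion_center(
            rng, class_label, config, brain_axes, head_center, radius, sinus_center, sinus_r
        )
        cand = _ellipse_mask(shape, center, (radius, radius * axis_ratio))
        if cand.any() and not ndimage.binary_dilation(cand)[~brain].any():
            lesion = cand
            break
    if lesion is None:
        raise GenerationError(
            f"lesion of radius {radius:.1f}px could not be placed inside the brain "
            f"ellipse for class {class_label} at image_size {s}"
        )

    tex = config.class_texture_params[class_label]
    sigma_tex = max(0.5, 256.0 / tex.frequency / (256.0 / s) / 4.0)
    smooth = _smooth_noise(rng, shape, sigma_tex)
    speckle = rng.standard_normal(shape)
    lesion_field = tex.base + tex.contrast * smooth + (1.0 - tex.homogeneity) * tex.contrast * speckle
    image[lesion] = lesion_field[lesion]

    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, shape)
    image = np.clip(image, 0.0, 1.0)

    mask = lesion.astype(np.uint8)
    border = trace_boundary(mask)
    rec = SliceRecord(
        pid=pid if pid is not None else f"PH{class_label}-{slice_seed:04d}",
        label=class_label,
        image=image,
        mask=mask,
        border=border,
    )
    return rec.validate()


def generate_dataset(config: PhantomConfig) -> list[SliceRecord]:
    """Generate ``3 * n_per_class`` phantoms, balanced over the three classes.

    Patient ids are assigned so that ``slices_per_patient`` consecutive slices
    of a class share a pid, enabling patient-aware fold stratification.
    Deterministic under ``config.seed``.
    """
    records: list[SliceRecord] = []
    for label in (1, 2, 3):
        for i in range(config.n_per_class):
            patient = i // config.slices_per_patient
            pid = f"PH{label}-{patient:03d}"
            records.append(generate_phantom(config, label, i, pid=pid))
    return records


def with_seed(config: PhantomConfig, seed: int) -> PhantomConfig:
    """Copy of ``config`` with a different seed (convenience for sweeps)."""
    return replace(config, seed=seed)
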