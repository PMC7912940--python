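"""Three-pathway multiscale CNN for center-pixel window classification.

Every N x N grayscale window (N = 65 in the reference configuration) is
processed in parallel by three convolutional pathways operating at large,
medium and small feature scales (11x11, 7x7, 3x3 kernels with 128, 96 and 64
maps).  Each pathway applies two stages of [conv (same padding) -> ReLU ->
3x3 max-pool, stride 2, ceiling-mode sizing].  The pathway outputs are
concatenated along the feature axis (288 maps at 16x16), passed through a
3x3 / 128-map convolution with ReLU and a 2x2 stride-2 max-pool, flattened
(128 x 8 x 8 = 8192 features), dropped out at rate 0.5, and fed to a single
fully connected layer with softmax over the four output labels
{healthy, meningioma, glioma, pituitary}.

The reference configuration has exactly 2,856,932 trainable parameters,
available both as a closed form (:func:`count_parameters`) and by enumerating
instantiated layer shapes.

The implementation is pure NumPy (float32): convolutions are computed as one
GEMM per kernel offset, which keeps memory flat even for the full-size
configuration, and every layer carries an explicit backward pass so the
network is trainable with SGD.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from itertools import product
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, ValidationError
from .augment import NormalizationStats

__all__ = [
    "NetworkConfig",
    "MultiscaleCNN",
    "build_network",
    "count_parameters",
    "enumerate_parameters",
    "forward_windows",
    "pooled_size",
    "save_checkpoint",
    "load_checkpoint",
]


def pooled_size(n: int, kernel: int, stride: int) -> int:
    """Output side of max-pooling with ceiling-mode sizing."""
    if n <= kernel:
        return 1
    return -((n - kernel) // -stride) + 1


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters; defaults are the reference network."""

    window_size: int = 65
    pathway_kernels: tuple[int, ...] = (11, 7, 3)
    pathway_maps: tuple[int, ...] = (128, 96, 64)
    convs_per_pathway: int = 2
    pathway_pool: tuple[int, int] = (3, 2)  # kernel, stride; ceiling-mode
    concat_kernel: int = 3
    concat_maps: int = 128
    concat_pool: tuple[int, int] = (2, 2)
    flat_features: int | None = None  # None -> derived from the spatial trace
    n_classes: int = 4
    dropout_rate: float = 0.5
    conv_bias: bool = True
    fc_bias: bool = True

    def __post_init__(self) -> None:
        if len(self.pathway_kernels) != len(self.pathway_maps):
            raise ConfigurationError("pathway_kernels and pathway_maps must have equal length")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.convs_per_pathway < 1:
            raise ConfigurationError("convs_per_pathway must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        derived = self.derived_flat_features()
        if self.flat_features is not None and self.flat_features != derived:
            raise ConfigurationError(
                f"flat_features {self.flat_features} inconsistent with spatial trace "
                f"(concat_maps x side^2 = {derived})"
            )

    def spatial_trace(self) -> list[int]:
        """Spatial side after each pooling stage (65 -> 32 -> 16 -> 8)."""
        side = self.window_size
        trace = [side]
        pk, ps = self.pathway_pool
        for _ in range(self.convs_per_pathway):
            side = pooled_size(side, pk, ps)
            trace.append(side)
        ck, cs = self.concat_pool
        trace.append(pooled_size(side, ck, cs))
        return trace

    def derived_flat_features(self) -> int:
        return self.concat_maps * self.spatial_trace()[-1] ** 2


def count_parameters(config: NetworkConfig) -> int:
    """Closed-form trainable-parameter count of the configured network.

    Per pathway with kernel k and m maps: conv1 has m*(k^2*1) weights, conv2
    (and any further stage) m*(k^2*m), each plus m biases; the concatenation
    conv has concat_maps*(ck^2 * sum(maps)) weights plus biases; the fully
    connected layer flat_features*n_classes plus n_classes biases.  For the
    reference configuration this totals 2,856,932.
    """
    total = 0
    for k, m in zip(config.pathway_kernels, config.pathway_maps):
        in_ch = 1
        for _ in range(config.convs_per_pathway):
            total += m * (k * k * in_ch) + (m if config.conv_bias else 0)
            in_ch = m
    total += config.concat_maps * (
        config.concat_kernel**2 * sum(config.pathway_maps)
    ) + (config.concat_maps if config.conv_bias else 0)
    flat = config.derived_flat_features()
    total += flat * config.n_classes + (config.n_classes if config.fc_bias else 0)
    return total


class _Conv2d:
    """Same-padding 2-D convolution, one GEMM per kernel offset.

    Activations flow in channels-first-of-batch layout ``(C, N, H, W)`` so
    each offset's contribution is a single ``(M, C) @ (C, N*H*W)`` product —
    large GEMMs keep single-CPU BLAS throughput high even for small batches.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, bias: bool, rng):
        fan_in = in_ch * kernel * kernel
        self.W = (rng.standard_normal((out_ch, in_ch, kernel, kernel)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32) if bias else None
        self.k = kernel
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._cols = None
        self._shape = None

    def _w2d(self) -> np.ndarray:
        # (M, k*k*C) matching the [offset, channel] ordering of the columns
        return np.ascontiguousarray(self.W.transpose(0, 2, 3, 1)).reshape(self.W.shape[0], -1)

    # column buffers above this size fall back to offset-wise accumulation
    _COLS_BYTES_LIMIT = 256 * 1024 * 1024

    def forward(self, x: np.ndarray, keep_cache: bool) -> np.ndarray:
        c, n, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        if not keep_cache and self.k * self.k * c * n * h * w * 4 > self._COLS_BYTES_LIMIT:
            out = np.zeros((self.W.shape[0], n * h * w), dtype=np.float32)
            for i, j in product(range(self.k), range(self.k)):
                xs = np.ascontiguousarray(xp[:, :, i : i + h, j : j + w]).reshape(c, -1)
                out += self.W[:, :, i, j] @ xs
            if self.b is not None:
                out += self.b[:, None]
            return out.reshape(self.W.shape[0], n, h, w)
        cols = np.empty((self.k * self.k, c, n, h, w), dtype=np.float32)
        for t, (i, j) in enumerate(product(range(self.k), range(self.k))):
            cols[t] = xp[:, :, i : i + h, j : j + w]
        cols2 = cols.reshape(self.k * self.k * c, n * h * w)
        out = self._w2d() @ cols2
        if self.b is not None:
            out += self.b[:, None]
        if keep_cache:
            self._cols = cols2
            self._shape = (c, n, h, w)
        return out.reshape(self.W.shape[0], n, h, w)

    def backward(self, dout: np.ndarray, need_dx: bool = True):
        m = self.W.shape[0]
        c, n, h, w = self._shape
        p = self.k // 2
        d2 = dout.reshape(m, n * h * w)
        if self.db is not None:
            self.db[:] = d2.sum(axis=1)
        dw2 = d2 @ self._cols.T
        self.dW[:] = dw2.reshape(m, self.k, self.k, c).transpose(0, 3, 1, 2)
        dx = None
        if need_dx:
            dcols = (self._w2d().T @ d2).reshape(self.k * self.k, c, n, h, w)
            dxp = np.zeros((c, n, h + 2 * p, w + 2 * p), dtype=np.float32)
            for t, (i, j) in enumerate(product(range(self.k), range(self.k))):
                dxp[:, :, i : i + h, j : j + w] += dcols[t]
            dx = dxp[:, :, p : p + h, p : p + w] if p else dxp
        self._cols = None
        return dx

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def grads(self):
        return [self.dW] + ([self.db] if self.db is not None else [])


class _ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, keep_cache: bool) -> np.ndarray:
        out = np.maximum(x, 0, out=x)  # in place: conv output is ours
        if keep_cache:
            self._mask = out > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout *= self._mask
        self._mask = None
        return dout


class _MaxPool2d:
    """Max pooling with ceiling-mode output sizing (-inf padding)."""

    def __init__(self, kernel: int, stride: int):
        self.k, self.s = kernel, stride
        self._argmax = None
        self._in_shape = None

    def forward(self, x: np.ndarray, keep_cache: bool) -> np.ndarray:
        c, n, h, w = x.shape
        oh, ow = pooled_size(h, self.k, self.s), pooled_size(w, self.k, self.s)
        ph, pw = (oh - 1) * self.s + self.k, (ow - 1) * self.s + self.k
        xp = np.full((c, n, ph, pw), -np.inf, dtype=x.dtype)
        xp[:, :, :h, :w] = x
        cands = np.empty((self.k * self.k, c, n, oh, ow), dtype=x.dtype)
        for t, (i, j) in enumerate(product(range(self.k), range(self.k))):
            cands[t] = xp[
                :, :, i : i + (oh - 1) * self.s + 1 : self.s, j : j + (ow - 1) * self.s + 1 : self.s
            ]
        best = cands.max(axis=0)
        if keep_cache:
            self._argmax = cands.argmax(axis=0).astype(np.int8)  # first max wins
            self._in_shape = (c, n, h, w)
            self._pad_shape = (c, n, ph, pw)
        return best

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, n, h, w = self._in_shape
        dxp = np.zeros(self._pad_shape, dtype=dout.dtype)
        oh, ow = dout.shape[2], dout.shape[3]
        for t, (i, j) in enumerate(product(range(self.k), range(self.k))):
            m = self._argmax == t
            if not m.any():
                continue
            dxp[:, :, i : i + (oh - 1) * self.s + 1 : self.s, j : j + (ow - 1) * self.s + 1 : self.s] += (
                dout * m
            )
        self._argmax = None
        return dxp[:, :, :h, :w]


class _Linear:
    def __init__(self, in_features: int, out_features: int, bias: bool, rng):
        self.W = (rng.standard_normal((out_features, in_features)) / np.sqrt(in_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._x = None

    def forward(self, x: np.ndarray, keep_cache: bool) -> np.ndarray:
        if keep_cache:
            self._x = x
        out = x @ self.W.T
        if self.b is not None:
            out += self.b
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[:] = dout.T @ self._x
        if self.db is not None:
            self.db[:] = dout.sum(axis=0)
        self._x = None
        return dout @ self.W

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def grads(self):
        return [self.dW] + ([self.db] if self.db is not None else [])


class MultiscaleCNN:
    """Trainable model handle: three pathways -> concat conv -> softmax head."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.pathways = []
        for k, m in zip(config.pathway_kernels, config.pathway_maps):
            stages = []
            in_ch = 1
            for _ in range(config.convs_per_pathway):
                stages.append(
                    (
                        _Conv2d(in_ch, m, k, config.conv_bias, rng),
                        _ReLU(),
                        _MaxPool2d(*config.pathway_pool),
                    )
                )
                in_ch = m
            self.pathways.append(stages)
        self.concat_conv = _Conv2d(
            sum(config.pathway_maps), config.concat_maps, config.concat_kernel, config.conv_bias, rng
        )
        self.concat_relu = _ReLU()
        self.concat_pool = _MaxPool2d(*config.concat_pool)
        self.flat_features = config.derived_flat_features()
        self.fc = _Linear(self.flat_features, config.n_classes, config.fc_bias, rng)
        self._dropout_mask = None
        self._path_channels = list(config.pathway_maps)

    # -- forward / backward -------------------------------------------------

    def forward_logits(
        self, x: np.ndarray, train: bool = False, dropout_rng=None
    ) -> np.ndarray:
        """Logits for a batch of shape (n, window, window) or (n, 1, w, w)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:  # (n, 1, h, w) -> (n, h, w)
            x = x[:, 0]
        n = x.shape[0]
        if x.shape[1] != self.config.window_size or x.shape[2] != self.config.window_size:
            raise ValidationError(
                f"patch side {x.shape[1:]} does not match window_size {self.config.window_size}"
            )
        if n == 0:
            return np.zeros((0, self.config.n_classes), dtype=np.float32)
        x = x[None]  # channels-first-of-batch layout (C=1, N, H, W)
        outs = []
        for stages in self.pathways:
            h = x
            for conv, relu, pool in stages:
                h = pool.forward(relu.forward(conv.forward(h, train), train), train)
            outs.append(h)
        h = np.concatenate(outs, axis=0)
        h = self.concat_pool.forward(
            self.concat_relu.forward(self.concat_conv.forward(h, train), train), train
        )
        flat = np.ascontiguousarray(h.transpose(1, 0, 2, 3)).reshape(n, -1)
        if train and self.config.dropout_rate > 0:
            rng = dropout_rng if dropout_rng is not None else np.random.default_rng()
            keep = 1.0 - self.config.dropout_rate
            self._dropout_mask = (rng.random(flat.shape) < keep).astype(np.float32) / np.float32(keep)
            flat = flat * self._dropout_mask
        return self.fc.forward(flat, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dflat = self.fc.backward(dlogits)
        if self._dropout_mask is not None:
            dflat = dflat * self._dropout_mask
            self._dropout_mask = None
        n = dlogits.shape[0]
        side = self.config.spatial_trace()[-1]
        dh = np.ascontiguousarray(
            dflat.reshape(n, self.config.concat_maps, side, side).transpose(1, 0, 2, 3)
        )
        dh = self.concat_conv.backward(
            self.concat_relu.backward(self.concat_pool.backward(dh))
        )
        offset = 0
        for stages, ch in zip(self.pathways, self._path_channels):
            dpath = np.ascontiguousarray(dh[offset : offset + ch])
            offset += ch
            for s_idx in range(len(stages) - 1, -1, -1):
                conv, relu, pool = stages[s_idx]
                dpath = conv.backward(
                    relu.backward(pool.backward(dpath)), need_dx=s_idx > 0
                )

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode class probabilities (dropout inactive)."""
        logits = self.forward_logits(x, train=False)
        return softmax(logits)

    # -- parameter access ---------------------------------------------------

    def _layers_with_params(self):
        for stages in self.pathways:
            for conv, _, _ in stages:
                yield conv
        yield self.concat_conv
        yield self.fc

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers_with_params() for p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._layers_with_params() for g in layer.grads()]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_network(config: NetworkConfig, seed: int = 0) -> MultiscaleCNN:
    """Instantiate the configured network with seeded initialization."""
    return MultiscaleCNN(config, seed=seed)


def enumerate_parameters(model: MultiscaleCNN) -> int:
    """Parameter count by enumerating instantiated array shapes (oracle for
    the closed form)."""
    return int(sum(p.size for p in model.parameters()))


def forward_windows(model: MultiscaleCNN, patches: np.ndarray) -> np.ndarray:
    """Class probabilities for a batch of standardized patches, order preserved."""
    return model.predict_proba(np.asarray(patches))


# -- checkpoints -----------------------------------------------------------


def _config_hash(config: NetworkConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_checkpoint(model: MultiscaleCNN, stats: NormalizationStats | None, path) -> None:
    """Weights as .npz plus a JSON sidecar with config and normalization stats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": p for i, p in enumerate(model.parameters())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "config": asdict(model.config),
        "config_hash": _config_hash(model.config),
        "stats": {"mean": stats.mean, "sd": stats.sd} if stats is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> tuple[MultiscaleCNN, NormalizationStats | None]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = sidecar["config"]
    for key in ("pathway_kernels", "pathway_maps", "pathway_pool", "concat_pool"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = NetworkConfig(**cfg_dict)
    if _config_hash(config) != sidecar["config_hash"]:
        raise ValidationError(f"{path}: config hash mismatch; sidecar corrupted")
    model = MultiscaleCNN(config, seed=0)
    with np.load(path.with_suffix(".npz")) as data:
        params = model.parameters()
        if len(data.files) != len(params):
            raise ValidationError(f"{path}: checkpoint has {len(data.files)} arrays, expected {len(params)}")
        for i, p in enumerate(params):
            stored = data[f"p{i}"]
            if stored.shape != p.shape:
                raise ValidationError(f"{path}: shape mismatch for parameter {i}")
            p[:] = stored
    stats = sidecar.get("stats")
    norm = NormalizationStats(**stats) if stats else None
    return model, norm


def toy_config(window_size: int = 17) -> NetworkConfig:
    """A desk-scale configuration used in examples and fast tests."""
    return NetworkConfig(
        window_size=window_size,
        pathway_kernels=(3, 3, 3),
        pathway_maps=(2, 2, 2),
        concat_maps=2,
    )
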