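"""Elastic-deformation augmentation, window sampling, and standardization.

Training follows the pipeline: each training slice is duplicated once by an
elastic deformation (doubling the fold), N x N windows are sampled around
tumor and healthy center pixels (150 positive / 325 negative per slice by
default), and all window pixels are standardized to zero mean and unit
variance using statistics pooled over the entire training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import AugmentationError, SamplingError, StatisticsError, ValidationError
from .phantom import SliceRecord, trace_boundary

__all__ = [
    "ElasticParams",
    "WindowSample",
    "NormalizationStats",
    "elastic_transform",
    "augment_fold",
    "sample_windows",
    "extract_window",
    "fit_standardization",
]

DEFAULT_N_POS = 150
DEFAULT_N_NEG = 325


@dataclass(frozen=True)
class ElasticParams:
    """Smooth random deformation field parameters.

    Per-pixel uniform[-1, 1] displacement fields are smoothed by a Gaussian of
    bandwidth ``sigma`` (px) and scaled to magnitude ``alpha`` (px).  Defaults
    scale with resolution: alpha = 0.1 x image side, sigma = 0.02 x image side
    are reasonable starting points for 256 px phantoms.
    """

    alpha: float = 25.6
    sigma: float = 5.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")


@dataclass
class WindowSample:
    """One N x N training patch centered on a labeled pixel."""

    patch: np.ndarray
    center: tuple[int, int]
    window_label: int  # 0 healthy, else the slice's tumor class
    source_index: int = -1


@dataclass(frozen=True)
class NormalizationStats:
    """Global pixel mean/sd pooled over all training windows."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise StatisticsError("sd must be > 0")

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float32) - np.float32(self.mean)) / np.float32(self.sd)


def elastic_transform(record: SliceRecord, params: ElasticParams) -> SliceRecord:
    """Warp image and mask by one shared smooth random displacement field.

    The image is resampled bilinearly, the mask with nearest-neighbor (so it
    stays binary), and the border polyline is re-derived from the warped mask.
    ``alpha = 0`` is the identity.  Deterministic under ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    shape = record.image.shape
    # draw both fields even when alpha == 0 so the stream is stable
    dr = ndimage.gaussian_filter(rng.uniform(-1, 1, shape), params.sigma) * params.alpha
    dc = ndimage.gaussian_filter(rng.uniform(-1, 1, shape), params.sigma) * params.alpha
    if params.alpha == 0:
        image, mask = record.image.copy(), record.mask.copy()
    else:
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        coords = np.stack([rr + dr, cc + dc])
        image = ndimage.map_coordinates(record.image, coords, order=1, mode="constant", cval=0.0)
        mask = ndimage.map_coordinates(record.mask, coords, order=0, mode="constant", cval=0)
    if not (mask == 1).any():
        raise AugmentationError(
            f"elastic transform (alpha={params.alpha}, seed={params.seed}) displaced "
            f"the lesion of {record.pid} out of frame"
        )
    return SliceRecord(
        pid=f"{record.pid}+elastic",
        label=record.label,
        image=image,
        mask=mask.astype(np.uint8),
        border=trace_boundary(mask),
    ).validate()


def augment_fold(
    records, params: ElasticParams, max_retries: int = 5
) -> list[SliceRecord]:
    """Originals followed by exactly one elastic copy per original (2n total).

    Each copy uses a seed derived from ``params.seed`` and the record's
    position, so the fold is reproducible; a copy whose lesion is displaced
    out of frame is reseeded up to ``max_retries`` times.
    """
    records = list(records)
    if not records:
        raise ValidationError("augment_fold requires a nonempty fold")
    ss = np.random.SeedSequence(params.seed)
    base_seeds = ss.generate_state(len(records) * (max_retries + 1)) >> 1  # keep < 2^31
    copies = []
    for i, rec in enumerate(records):
        last_err = None
        for attempt in range(max_retries + 1):
            seed = int(base_seeds[i * (max_retries + 1) + attempt])
            try:
                copies.append(
                    elastic_transform(
                        rec, ElasticParams(alpha=params.alpha, sigma=params.sigma, seed=seed)
                    )
                )
                break
            except AugmentationError as err:  # pragma: no cover - rare geometry
                last_err = err
        else:  # pragma: no cover
            raise last_err
    return records + copies


def extract_window(image: np.ndarray, center: tuple[int, int], window_size: int) -> np.ndarray:
    """N x N patch centered on ``center``, zero-padded past the image edge."""
    half = window_size // 2
    r, c = center
    patch = np.zeros((window_size, window_size), dtype=image.dtype)
    r0, r1 = max(0, r - half), min(image.shape[0], r - half + window_size)
    c0, c1 = max(0, c - half), min(image.shape[1], c - half + window_size)
    patch[r0 - (r - half) : r1 - (r - half), c0 - (c - half) : c1 - (c - half)] = image[
        r0:r1, c0:c1
    ]
    return patch


def sample_windows(
    record: SliceRecord,
    n_pos: int = DEFAULT_N_POS,
    n_neg: int = DEFAULT_N_NEG,
    window_size: int = 65,
    seed: int = 0,
    source_index: int = -1,
) -> list[WindowSample]:
    """Sample training windows from one slice.

    Exactly ``n_pos`` windows centered on tumor pixels (labeled with the
    slice's class) and ``n_neg`` centered on healthy pixels (label 0, drawn
    from ALL non-tumor pixels including skull and background — the method
    performs no skull stripping, so it must learn such negatives).  Centers
    are drawn uniformly without replacement; deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    fg = np.flatnonzero(record.mask.ravel() == 1)
    bg = np.flatnonzero(record.mask.ravel() == 0)
    if len(fg) < n_pos:
        raise SamplingError(
            f"{record.pid}: only {len(fg)} tumor pixels, cannot draw {n_pos} positive centers"
        )
    if len(bg) < n_neg:
        raise SamplingError(
            f"{record.pid}: only {len(bg)} healthy pixels, cannot draw {n_neg} negative centers"
        )
    w = record.image.shape[1]
    samples = []
    for flat_idx, label, count in (
        (fg, record.label, n_pos),
        (bg, 0, n_neg),
    ):
        chosen = rng.choice(flat_idx, size=count, replace=False)
        for f in chosen:
            center = (int(f) // w, int(f) % w)
            samples.append(
                WindowSample(
                    patch=extract_window(record.image, center, window_size),
                    center=center,
                    window_label=int(label),
                    source_index=source_index,
                )
            )
    return samples


def fit_standardization(windows) -> NormalizationStats:
    """Pooled pixel mean/sd over all training windows (population sd).

    Accepts :class:`WindowSample` objects or bare patch arrays (including one
    stacked ``(n, N, N)`` array).
    """
    windows = list(windows)
    if not windows:
        raise ValidationError("fit_standardization requires at least one window")
    pool = np.concatenate(
        [
            np.asarray(w.patch if hasattr(w, "patch") else w, dtype=np.float64).ravel()
            for w in windows
        ]
    )
    mean = float(pool.mean())
    sd = float(pool.std())
    if sd == 0:
        raise StatisticsError("pooled pixel variance is zero; cannot standardize")
    return NormalizationStats(mean=mean, sd=sd)
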