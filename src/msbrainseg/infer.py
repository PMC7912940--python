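"""Sliding-window per-pixel labeling of a full slice.

Every ``stride``-th pixel in both axes is taken as a window center; its
zero-padded N x N neighborhood is standardized with the training statistics
and classified by the network, and the argmax class is written at the center.
With ``stride == 1`` (the reference procedure) every pixel receives the label
of its own centered window; for larger strides the unsampled pixels take the
label of their nearest sampled center, ties broken toward the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augment import NormalizationStats
from .exceptions import ValidationError

__all__ = ["LabelMap", "segment_slice", "argmax_label", "labelmap_to_png"]

# label -> RGB, the rendering convention for class tags
PALETTE = {0: (0, 0, 0), 1: (255, 0, 0), 2: (0, 255, 0), 3: (0, 0, 255)}


@dataclass
class LabelMap:
    """Per-pixel predicted labels P_ij in {0, 1, 2, 3} for one slice."""

    labels: np.ndarray
    stride: int = 1
    source_index: int = -1

    def validate(self) -> "LabelMap":
        if self.labels.ndim != 2:
            raise ValidationError("label map must be 2-D")
        if not np.isin(np.unique(self.labels), (0, 1, 2, 3)).all():
            raise ValidationError("label map values must be in {0,1,2,3}")
        return self


def argmax_label(probs: np.ndarray) -> int:
    """Index of the maximal probability; ties break toward the smallest label."""
    return int(np.argmax(np.asarray(probs)))


def segment_slice(
    model,
    stats: NormalizationStats,
    image: np.ndarray,
    window_size: int | None = None,
    stride: int = 1,
    batch_size: int = 512,
    source_index: int = -1,
) -> LabelMap:
    """Label every pixel of ``image`` by sliding-window classification.

    ``model`` is anything exposing ``predict_proba(batch) -> (n, n_classes)``
    (a trained :class:`~msbrainseg.network.MultiscaleCNN` or a stub).
    """
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    image = np.asarray(image, dtype=np.float32)
    if window_size is None:
        window_size = model.config.window_size
    h, w = image.shape
    half = window_size // 2
    padded = np.pad(image, half)
    windows = np.lib.stride_tricks.sliding_window_view(padded, (window_size, window_size))
    rows = np.arange(0, h, stride)
    cols = np.arange(0, w, stride)
    centers_r, centers_c = np.meshgrid(rows, cols, indexing="ij")
    flat_r, flat_c = centers_r.ravel(), centers_c.ravel()

    sparse = np.empty(flat_r.shape[0], dtype=np.int64)
    for start in range(0, flat_r.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        patches = windows[flat_r[sl], flat_c[sl]]
        probs = model.predict_proba(stats.apply(patches))
        sparse[sl] = np.argmax(probs, axis=1)  # first max = smallest label
    sparse = sparse.reshape(len(rows), len(cols))

    if stride == 1:
        labels = sparse
    else:
        row_map = np.abs(np.arange(h)[:, None] - rows[None, :]).argmin(axis=1)
        col_map = np.abs(np.arange(w)[:, None] - cols[None, :]).argmin(axis=1)
        labels = sparse[row_map][:, col_map]
    return LabelMap(labels=labels, stride=stride, source_index=source_index).validate()


def labelmap_to_png(label_map: LabelMap, path) -> None:
    """Serialize a label map as an indexed-color PNG (black/red/green/blue)."""
    from PIL import Image

    rgb = np.zeros((*label_map.labels.shape, 3), dtype=np.uint8)
    for label, color in PALETTE.items():
        rgb[label_map.labels == label] = color
    Image.fromarray(rgb).save(path)
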