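"""Slice classification, segmentation metrics, and report assembly.

A label map P is reduced to a slice-level tumor-type call by the
classification function: for each class l in {1, 2, 3} the ratio

    f_l = |{P == l}| / |{P > 0}|

is computed, ratios at or below the confidence threshold tau_c are zeroed,
and the predicted label l_p is the argmax of the surviving ratios, or -1
(non-classified) when none survive or the map contains no tumor pixels.

Segmentation quality is scored per slice against the ground-truth mask T with
P1 = {P == l_gt} (the pixels carrying the true class):

    Dice        = 2 TP / (2 TP + FP + FN)
    Sensitivity = TP / (TP + FN)
    pttas       = |P1| / |{P > 0}|   (precision of the predicted tumor type)

Slice calls are tallied into a 3x3 confusion matrix with a per-class
non-classified column; the tumor classification accuracy is the diagonal sum
over ALL slices, non-classified ones included in the denominator.  Printed
summaries truncate (not round) 3-decimal values, matching the convention of
the reference results tables; per-class sensitivities are rounded to 2
decimals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .infer import LabelMap
from .phantom import SliceRecord

__all__ = [
    "ClassificationResult",
    "SliceMetrics",
    "ConfusionReport",
    "EvaluationReport",
    "classify_slice",
    "slice_metrics",
    "macro_average",
    "truncate3",
    "build_confusion",
    "threshold_precision_curve",
    "render_overlay",
    "metric_histogram",
    "build_report",
]

CLASSES = (1, 2, 3)
NON_CLASSIFIED = -1


def truncate3(x: float) -> float:
    """Truncate toward zero to 3 decimals (printed-table convention)."""
    return math.trunc(x * 1000) / 1000


@dataclass
class ClassificationResult:
    """Per-class ratios f_l, the threshold used, and the slice-level call."""

    ratios: np.ndarray  # f_l for l = 1, 2, 3, before thresholding
    tau_c: float
    lp: int  # in {-1, 1, 2, 3}


@dataclass
class SliceMetrics:
    dice: float
    sensitivity: float
    pttas: float
    tp: int
    fp: int
    fn: int


def _labels_array(label_map) -> np.ndarray:
    return label_map.labels if isinstance(label_map, LabelMap) else np.asarray(label_map)


def _ratios(labels: np.ndarray) -> np.ndarray:
    total = int((labels > 0).sum())
    if total == 0:
        return np.zeros(3)
    return np.array([(labels == l).sum() / total for l in CLASSES])


def _label_from_ratios(ratios: np.ndarray, tau_c: float) -> int:
    surviving = np.where(ratios > tau_c, ratios, 0.0)
    if not (surviving > 0).any():
        return NON_CLASSIFIED
    return int(np.argmax(surviving)) + 1  # first max = smallest label on ties


def classify_slice(label_map, tau_c: float) -> ClassificationResult:
    """Apply the confidence-thresholded classification function to one map."""
    if not 0 <= tau_c <= 1:
        raise ValidationError("tau_c must be in [0, 1]")
    ratios = _ratios(_labels_array(label_map))
    return ClassificationResult(ratios=ratios, tau_c=tau_c, lp=_label_from_ratios(ratios, tau_c))


def slice_metrics(label_map, record: SliceRecord) -> SliceMetrics:
    """Dice, Sensitivity and pttas of one predicted map against the record."""
    labels = _labels_array(label_map)
    if labels.shape != record.mask.shape:
        raise ValidationError(f"label map shape {labels.shape} != mask shape {record.mask.shape}")
    p1 = labels == record.label
    t1 = record.mask > 0
    tp = int((p1 & t1).sum())
    fp = int(p1.sum()) - tp
    fn = int(t1.sum()) - tp
    denom = 2 * tp + fp + fn
    dice = 2 * tp / denom if denom > 0 else 1.0
    sensitivity = tp / (tp + fn) if tp + fn > 0 else 1.0
    n_tumor_labeled = int((labels > 0).sum())
    pttas = p1.sum() / n_tumor_labeled if n_tumor_labeled > 0 else 0.0
    return SliceMetrics(dice=dice, sensitivity=sensitivity, pttas=float(pttas), tp=tp, fp=fp, fn=fn)


def macro_average(values, truncate: bool = False) -> float:
    """Arithmetic mean over per-class values; optionally truncated to 3
    decimals, the convention used when matching printed summary rows."""
    values = list(values)
    if not values:
        raise ValidationError("macro_average requires at least one value")
    mean = float(np.mean(values))
    return truncate3(mean) if truncate else mean


@dataclass
class ConfusionReport:
    """3x3 confusion counts with a non-classified column and derived rates."""

    confusion: np.ndarray  # [true-1, predicted-1]
    non_classified: np.ndarray  # per true class
    n_total: int

    @property
    def accuracy(self) -> float:
        """Diagonal sum over all slices, non-classified in the denominator."""
        return float(np.trace(self.confusion)) / self.n_total if self.n_total else 0.0

    @property
    def accuracy_printed(self) -> float:
        return truncate3(self.accuracy)

    @property
    def per_class_sensitivity(self) -> np.ndarray:
        """Diagonal over the full true-class count (incl. non-classified)."""
        row_totals = self.confusion.sum(axis=1) + self.non_classified
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(row_totals > 0, np.diag(self.confusion) / row_totals, 0.0)
        return out

    @property
    def per_class_sensitivity_printed(self) -> list[float]:
        return [round(float(s), 2) for s in self.per_class_sensitivity]


def build_confusion(results) -> ConfusionReport:
    """Tally (true label, ClassificationResult) pairs into a confusion report."""
    confusion = np.zeros((3, 3), dtype=np.int64)
    non_classified = np.zeros(3, dtype=np.int64)
    n = 0
    for true_label, res in results:
        if true_label not in CLASSES:
            raise ValidationError(f"true label {true_label} outside {{1,2,3}}")
        lp = res.lp if isinstance(res, ClassificationResult) else int(res)
        n += 1
        if lp == NON_CLASSIFIED:
            non_classified[true_label - 1] += 1
        elif lp in CLASSES:
            confusion[true_label - 1, lp - 1] += 1
        else:
            raise ValidationError(f"predicted label {lp} outside {{-1,1,2,3}}")
    return ConfusionReport(confusion=confusion, non_classified=non_classified, n_total=n)


def threshold_precision_curve(ratio_sets, taus) -> list[tuple[float, float, int]]:
    """Accuracy and classified count as the confidence threshold sweeps.

    ``ratio_sets`` holds (true label, pre-threshold ratio vector) pairs; for
    each tau the stored ratios are re-thresholded and re-classified.  Returns
    (tau, precision, n_classified) triples; n_classified is non-increasing.
    """
    ratio_sets = [(t, np.asarray(r, dtype=float)) for t, r in ratio_sets]
    out = []
    for tau in taus:
        if not 0 <= tau <= 1:
            raise ValidationError("thresholds must lie in [0, 1]")
        correct = 0
        n_classified = 0
        for true_label, ratios in ratio_sets:
            lp = _label_from_ratios(ratios, tau)
            if lp != NON_CLASSIFIED:
                n_classified += 1
                if lp == true_label:
                    correct += 1
        out.append((float(tau), correct / len(ratio_sets) if ratio_sets else 0.0, n_classified))
    return out


def render_overlay(label_map, record: SliceRecord, mode: str = "segmentation") -> np.ndarray:
    """RGB uint8 overlay of a prediction on the grayscale slice.

    ``segmentation`` mode paints the predicted tumor region {P > 0} red, the
    ground-truth mask green, and their intersection yellow.  ``class-tags``
    mode paints label 1 red, 2 green, 3 blue.
    """
    labels = _labels_array(label_map)
    if labels.shape != record.image.shape:
        raise ValidationError("label map and image shapes differ")
    img = record.image.astype(float)
    lo, hi = img.min(), img.max()
    gray = ((img - lo) / (hi - lo) * 255 if hi > lo else np.zeros_like(img)).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)
    if mode == "segmentation":
        pred = labels > 0
        gt = record.mask > 0
        rgb[pred & ~gt] = (255, 0, 0)
        rgb[gt & ~pred] = (0, 255, 0)
        rgb[pred & gt] = (255, 255, 0)
    elif mode == "class-tags":
        for l, color in ((1, (255, 0, 0)), (2, (0, 255, 0)), (3, (0, 0, 255))):
            rgb[labels == l] = color
    else:
        raise ValidationError(f"unknown overlay mode {mode!r}")
    return rgb


def metric_histogram(values, bins: int = 20, value_range=(0.0, 1.0)) -> pd.DataFrame:
    """Binned counts of a per-slice metric (histogram-figure analogue)."""
    counts, edges = np.histogram(np.asarray(list(values), dtype=float), bins=bins, range=value_range)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


@dataclass
class EvaluationReport:
    """Per-slice metrics plus the aggregate confusion summary."""

    per_slice: list[dict] = field(default_factory=list)
    confusion: ConfusionReport | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_slice)

    def to_json(self) -> str:
        payload = {
            "per_slice": self.per_slice,
            "confusion": self.confusion.confusion.tolist() if self.confusion else None,
            "non_classified": self.confusion.non_classified.tolist() if self.confusion else None,
            "accuracy": self.confusion.accuracy if self.confusion else None,
            "per_class_sensitivity": (
                [float(s) for s in self.confusion.per_class_sensitivity] if self.confusion else None
            ),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def build_report(entries) -> EvaluationReport:
    """Assemble a report from (index, true label, SliceMetrics,
    ClassificationResult) tuples."""
    per_slice = []
    pairs = []
    for index, true_label, metrics, classification in entries:
        per_slice.append(
            {
                "index": int(index),
                "true_label": int(true_label),
                "predicted_label": int(classification.lp),
                "dice": metrics.dice,
                "sensitivity": metrics.sensitivity,
                "pttas": metrics.pttas,
                "tp": metrics.tp,
                "fp": metrics.fp,
                "fn": metrics.fn,
                "ratios": [float(r) for r in classification.ratios],
                "tau_c": classification.tau_c,
            }
        )
        pairs.append((true_label, classification))
    return EvaluationReport(per_slice=per_slice, confusion=build_confusion(pairs))
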