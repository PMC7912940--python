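"""Reading and writing slice records, and train/test fold handling.

Two on-disk layouts are supported, dispatched on file signature:

* the real dataset's layout — one MATLAB-v7.3 (HDF5) file per slice with a
  ``cjdata`` group holding ``pid``, ``label``, ``image``, ``tumorBorder`` (a
  flat 1-based coordinate vector) and ``tumorMask``;
* the phantom fixture layout — one HDF5 file per record with the same field
  names at the file root, 0-based (row, col) border, plus a CSV manifest.

Internally everything is 0-based (row, col), row-major.  The real layout's
border vector does not define its axis order, so the reader validates border
points against the mask and flips the (x, y) interpretation when more than
half the points miss foreground.

Fold files are JSON with five arrays of 0-based test indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError
from .phantom import SliceRecord

__all__ = [
    "FoldSpec",
    "read_record",
    "write_record",
    "write_dataset",
    "read_manifest",
    "make_stratified_folds",
    "load_fold_indices",
    "save_fold_indices",
]

_FIELDS = ("pid", "label", "image", "tumorBorder", "tumorMask")


@dataclass(frozen=True)
class FoldSpec:
    """One cross-validation fold: disjoint train/test index sets."""

    fold_id: int
    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.train_indices) & set(self.test_indices):
            raise ValidationError(f"fold {self.fold_id}: train and test overlap")


def _decode_pid(raw) -> str:
    arr = np.asarray(raw)
    if arr.dtype.kind in "US":
        val = arr.reshape(-1)[0]
        return val.decode() if isinstance(val, bytes) else str(val)
    # MATLAB stores strings as uint16 character arrays
    return "".join(chr(int(c)) for c in arr.reshape(-1))


def _border_from_flat(flat: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Normalize a real-layout border vector to 0-based (row, col).

    The source stores a flat [a1, b1, a2, b2, ...] vector, 1-based, without
    defining whether (a, b) is (x, y) or (row, col).  Both interpretations are
    scored against the mask; the one landing on foreground wins.
    """
    pts = np.asarray(flat, dtype=float).reshape(-1, 2)
    h, w = mask.shape

    def score(rowcol: np.ndarray) -> float:
        rr = np.clip(np.round(rowcol[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(rowcol[:, 1]).astype(int), 0, w - 1)
        return float(mask[rr, cc].mean())

    as_rowcol = pts - 1.0
    as_xy = pts[:, ::-1] - 1.0
    chosen = as_rowcol if score(as_rowcol) >= 0.5 else as_xy
    out = np.round(chosen).astype(np.int64)
    out[:, 0] = np.clip(out[:, 0], 0, h - 1)
    out[:, 1] = np.clip(out[:, 1], 0, w - 1)
    return out


def read_record(path) -> SliceRecord:
    """Read one slice record (real or phantom layout) and validate it."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "cjdata" in f:
            group, real_layout = f["cjdata"], True
        else:
            group, real_layout = f, False
        missing = [name for name in _FIELDS if name not in group]
        if missing:
            raise FormatError(f"{path}: missing field(s) {missing}")
        pid = _decode_pid(group["pid"][()])
        label_arr = np.asarray(group["label"][()]).reshape(-1)
        label = int(label_arr[0])
        image = np.asarray(group["image"][()], dtype=np.float64)
        mask = np.asarray(group["tumorMask"][()])
        border_raw = np.asarray(group["tumorBorder"][()])

    if label not in (1, 2, 3):
        raise ValidationError(f"{path}: label {label} outside {{1,2,3}}")
    if mask.shape != image.shape:
        raise ValidationError(f"{path}: mask shape {mask.shape} != image shape {image.shape}")
    mask = (mask > 0).astype(np.uint8)
    if real_layout:
        border = _border_from_flat(border_raw, mask)
        # delineations are polylines; snap any off-mask rounding onto foreground
        on = mask[border[:, 0], border[:, 1]].astype(bool)
        border = border[on] if on.any() else border
    else:
        border = np.asarray(border_raw, dtype=np.int64).reshape(-1, 2)
    return SliceRecord(pid=pid, label=label, image=image, mask=mask, border=border).validate()


def write_record(record: SliceRecord, path) -> None:
    """Write a record in the phantom fixture layout (readable by read_record)."""
    record.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("pid", data=np.bytes_(record.pid))
        f.create_dataset("label", data=np.int64(record.label))
        f.create_dataset("image", data=record.image.astype(np.float64))
        f.create_dataset("tumorMask", data=record.mask.astype(np.uint8))
        f.create_dataset("tumorBorder", data=np.asarray(record.border, dtype=np.int64))


def write_dataset(records, directory) -> pd.DataFrame:
    """Write records plus a CSV manifest (pid, label, filename); returns it."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        fname = f"slice_{i:04d}.h5"
        write_record(rec, directory / fname)
        rows.append({"pid": rec.pid, "label": rec.label, "filename": fname})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def read_manifest(directory) -> pd.DataFrame:
    return pd.read_csv(Path(directory) / "manifest.csv")


def make_stratified_folds(
    labels,
    pids=None,
    k: int = 5,
    seed: int = 0,
    patient_aware: bool = True,
) -> list[FoldSpec]:
    """Stratified k-fold split of record indices.

    Test sets partition the records; each class's test-set share stays within
    one record of its global share (exact when class sizes divide k and, with
    ``patient_aware``, patients contribute equal slice counts).  When
    ``patient_aware`` and ``pids`` are given, all slices of a patient land in
    the same test set.  Deterministic under ``seed``.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValidationError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    short = classes[counts < k]
    if short.size:
        raise ValidationError(f"class(es) {short.tolist()} have fewer than k={k} records")

    rng = np.random.default_rng(seed)
    if pids is None or not patient_aware:
        groups = [[i] for i in range(n)]
        group_label = labels
    else:
        pids = np.asarray(pids)
        uniq = pd.unique(pids)
        groups = [np.nonzero(pids == p)[0].tolist() for p in uniq]
        # mixed-class patients (absent from phantoms) stratify by first slice
        group_label = np.array([labels[g[0]] for g in groups])

    test_sets: list[list[int]] = [[] for _ in range(k)]
    fold_totals = np.zeros(k, dtype=int)
    for cls in classes:
        idx = [gi for gi in range(len(groups)) if group_label[gi] == cls]
        rng.shuffle(idx)
        # largest patient groups first, each to the currently lightest fold
        idx.sort(key=lambda gi: -len(groups[gi]))
        cls_totals = np.zeros(k, dtype=int)
        for gi in idx:
            # prefer folds light in this class, break ties by overall load
            target = int(np.lexsort((fold_totals, cls_totals))[0])
            test_sets[target].extend(groups[gi])
            cls_totals[target] += len(groups[gi])
            fold_totals[target] += len(groups[gi])

    all_idx = set(range(n))
    folds = []
    for fid in range(k):
        test = tuple(sorted(test_sets[fid]))
        train = tuple(sorted(all_idx - set(test)))
        folds.append(FoldSpec(fold_id=fid + 1, train_indices=train, test_indices=test))
    _check_partition(folds, n)
    return folds


def _check_partition(folds: list[FoldSpec], n_records: int) -> None:
    seen: list[int] = []
    for f in folds:
        seen.extend(f.test_indices)
        union = set(f.train_indices) | set(f.test_indices)
        if union != set(range(n_records)):
            raise ValidationError(f"fold {f.fold_id}: train+test do not cover all records")
    if len(seen) != len(set(seen)):
        raise ValidationError("test sets overlap across folds")
    if set(seen) != set(range(n_records)):
        raise ValidationError("test sets do not partition the records")


def save_fold_indices(folds: list[FoldSpec], path) -> None:
    payload = {"test_indices": [list(f.test_indices) for f in folds]}
    Path(path).write_text(json.dumps(payload))


def load_fold_indices(path, n_records: int) -> list[FoldSpec]:
    """Load stored test-index lists; train sets are their complements."""
    payload = json.loads(Path(path).read_text())
    lists = payload["test_indices"] if isinstance(payload, dict) else payload
    if len(lists) != 5:
        raise ValidationError(f"expected 5 fold index lists, got {len(lists)}")
    folds = []
    all_idx = set(range(n_records))
    for fid, test in enumerate(lists, start=1):
        test_arr = [int(i) for i in test]
        bad = [i for i in test_arr if i < 0 or i >= n_records]
        if bad:
            raise ValidationError(f"fold {fid}: index(es) {bad} out of range [0, {n_records})")
        train = tuple(sorted(all_idx - set(test_arr)))
        folds.append(FoldSpec(fold_id=fid, train_indices=train, test_indices=tuple(sorted(test_arr))))
    _check_partition(folds, n_records)
    return folds
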