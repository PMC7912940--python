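"""Window-level training with SGD + momentum and 5-fold orchestration.

The reference schedule trains for 80 epochs of stochastic gradient descent
with momentum 0.9, starting at learning rate 0.005, with a stepwise
exponential decay every 20 epochs (decay factor configurable; 0.1 by
default).  The loss is categorical cross-entropy over the four pixel labels.
The full pipeline per fold is:

    augment_fold  ->  sample_windows per slice  ->  fit_standardization
                  ->  standardize  ->  shuffled mini-batch SGD

Normalization statistics come from the training windows only and are reused
unchanged when testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import evaluate as ev
from .augment import (
    DEFAULT_N_NEG,
    DEFAULT_N_POS,
    ElasticParams,
    NormalizationStats,
    augment_fold,
    fit_standardization,
    sample_windows,
)
from .dataset_io import FoldSpec
from .exceptions import TrainingError, ValidationError
from .infer import segment_slice
from .network import MultiscaleCNN, NetworkConfig, build_network, softmax

__all__ = [
    "TrainConfig",
    "lr_schedule",
    "train_fold",
    "run_cross_validation",
    "FoldResult",
    "aggregate_report",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule; defaults follow the reference setup."""

    epochs: int = 80
    lr0: float = 0.005
    momentum: float = 0.9
    lr_decay_every: int = 20
    lr_decay_factor: float = 0.1
    batch_size: int = 128
    seed: int = 0
    n_pos: int = DEFAULT_N_POS
    n_neg: int = DEFAULT_N_NEG

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.lr0 <= 0:
            raise ValidationError("lr0 must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValidationError("momentum must be in [0, 1)")
        if not 0 < self.lr_decay_factor <= 1:
            raise ValidationError("lr_decay_factor must be in (0, 1]")
        if self.lr_decay_every < 1:
            raise ValidationError("lr_decay_every must be >= 1")


def lr_schedule(config: TrainConfig, epoch: int) -> float:
    """Stepwise exponential decay: lr0 * factor^floor(epoch / decay_every)."""
    if not 0 <= epoch < config.epochs:
        raise ValidationError(f"epoch {epoch} outside [0, {config.epochs})")
    return config.lr0 * config.lr_decay_factor ** (epoch // config.lr_decay_every)


def _build_window_arrays(records, net_config, sample_seeds, n_pos, n_neg):
    patches, labels = [], []
    for idx, rec in enumerate(records):
        for wsample in sample_windows(
            rec,
            n_pos=n_pos,
            n_neg=n_neg,
            window_size=net_config.window_size,
            seed=int(sample_seeds[idx]),
            source_index=idx,
        ):
            patches.append(wsample.patch)
            labels.append(wsample.window_label)
    x = np.stack(patches).astype(np.float32)
    y = np.asarray(labels, dtype=np.int64)
    return x, y


def train_fold(
    train_records,
    net_config: NetworkConfig,
    train_config: TrainConfig,
    aug_params: ElasticParams,
) -> tuple[MultiscaleCNN, NormalizationStats, list[dict]]:
    """Train one model on one fold's training slices.

    Returns the trained model, the pooled normalization statistics, and a
    per-epoch log of ``{"epoch", "lr", "mean_loss"}``.  Deterministic under
    ``train_config.seed``.
    """
    train_records = list(train_records)
    if not train_records:
        raise ValidationError("train_fold requires a nonempty training set")

    ss = np.random.SeedSequence(train_config.seed)
    aug_seed, init_seed, shuffle_seed, dropout_seed, sample_root = (
        int(s) for s in (ss.generate_state(5) >> 1)
    )
    augmented = augment_fold(
        train_records, ElasticParams(alpha=aug_params.alpha, sigma=aug_params.sigma, seed=aug_seed)
    )
    sample_seeds = np.random.SeedSequence(sample_root).generate_state(len(augmented)) >> 1
    x, y = _build_window_arrays(
        augmented, net_config, sample_seeds, train_config.n_pos, train_config.n_neg
    )
    stats = fit_standardization([x])  # pooled over all window pixels
    x = stats.apply(x)

    model = build_network(net_config, seed=init_seed)
    velocity = [np.zeros_like(p) for p in model.parameters()]
    shuffle_rng = np.random.default_rng(shuffle_seed)
    dropout_rng = np.random.default_rng(dropout_seed)
    n = x.shape[0]
    onehot_eye = np.eye(net_config.n_classes, dtype=np.float32)

    log = []
    for epoch in range(train_config.epochs):
        lr = lr_schedule(train_config, epoch)
        perm = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, train_config.batch_size):
            idx = perm[start : start + train_config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward_logits(xb, train=True, dropout_rng=dropout_rng)
            probs = softmax(logits)
            batch_loss = float(-np.log(np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)).mean())
            if not np.isfinite(batch_loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch starting at {start}"
                )
            losses.append(batch_loss)
            dlogits = (probs - onehot_eye[yb]) / np.float32(len(yb))
            model.backward(dlogits)
            params, grads = model.parameters(), model.gradients()
            for p, g, v in zip(params, grads, velocity):
                v *= np.float32(train_config.momentum)
                v -= np.float32(lr) * g
                p += v
        log.append({"epoch": epoch, "lr": lr, "mean_loss": float(np.mean(losses))})
    return model, stats, log


@dataclass
class FoldResult:
    fold_id: int
    model: MultiscaleCNN
    stats: NormalizationStats
    log: list[dict]
    report: ev.EvaluationReport


def run_cross_validation(
    records,
    folds: list[FoldSpec],
    net_config: NetworkConfig,
    train_config: TrainConfig,
    aug_params: ElasticParams,
    tau_c: float = 0.75,
    stride: int = 1,
    infer_batch_size: int = 512,
) -> list[FoldResult]:
    """Train and evaluate one model per fold; per-fold seeds derive from
    ``train_config.seed`` and the fold id, so the whole run is reproducible."""
    records = list(records)
    results = []
    for fold in folds:
        fold_seed = int(np.random.SeedSequence([train_config.seed, fold.fold_id]).generate_state(1)[0] >> 1)
        fold_train_config = TrainConfig(
            epochs=train_config.epochs,
            lr0=train_config.lr0,
            momentum=train_config.momentum,
            lr_decay_every=train_config.lr_decay_every,
            lr_decay_factor=train_config.lr_decay_factor,
            batch_size=train_config.batch_size,
            seed=fold_seed,
            n_pos=train_config.n_pos,
            n_neg=train_config.n_neg,
        )
        try:
            model, stats, log = train_fold(
                [records[i] for i in fold.train_indices], net_config, fold_train_config, aug_params
            )
            entries = []
            for idx in fold.test_indices:
                rec = records[idx]
                label_map = segment_slice(
                    model,
                    stats,
                    rec.image,
                    window_size=net_config.window_size,
                    stride=stride,
                    batch_size=infer_batch_size,
                    source_index=idx,
                )
                entries.append(
                    (idx, rec.label, ev.slice_metrics(label_map, rec), ev.classify_slice(label_map, tau_c))
                )
        except Exception as err:
            raise type(err)(f"fold {fold.fold_id}: {err}") from err
        results.append(
            FoldResult(fold_id=fold.fold_id, model=model, stats=stats, log=log, report=ev.build_report(entries))
        )
    return results


def aggregate_report(fold_results: list[FoldResult]) -> ev.EvaluationReport:
    """Concatenate per-slice results over all folds into one report (the
    all-slices aggregation used for whole-dataset summaries)."""
    per_slice = [row for fr in fold_results for row in fr.report.per_slice]
    pairs = [
        (row["true_label"], ev.ClassificationResult(
            ratios=np.asarray(row["ratios"]), tau_c=row["tau_c"], lp=row["predicted_label"]
        ))
        for row in per_slice
    ]
    return ev.EvaluationReport(per_slice=per_slice, confusion=ev.build_confusion(pairs))
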