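"""Evaluation protocol: confusion tables, P/R/F-measure, PR curves, LOOCV.

Binary ablation detection is scored per held-out procedure with precision
``p = tp/(tp+fp)``, recall ``r = tp/(tp+fn)``, and the F-measure

    f1 = 2 / (1/r + 1/p),

the harmonic mean of precision and recall.  Zero denominators yield an
*undefined* sentinel (NaN) that propagates to f1 and is excluded from
averages — never coerced to 0 or 1.  Cumulative results sum the per-fold
confusion tables cell-wise.  Validation procedures are evaluated complete
and imbalanced; balancing and augmentation apply to training data only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .backbone import BackboneConfig, BinaryClassifier, DESK_TRAIN, TrainConfig, build_model, train
from .baseline import SvmBaseline
from .data import AnnotatedDataset, SplitPlan, balanced_subsample
from .pipeline import CompleteResult, classify_frames, filter_binary_predictions, segment_timeline

__all__ = [
    "f_measure",
    "ConfusionTable",
    "MetricsReport",
    "FoldResult",
    "StudyReport",
    "confusion",
    "prf",
    "pr_curve",
    "cross_validate_cnn",
    "evaluate_study",
    "UNDEFINED",
]

#: Sentinel for metrics with a zero denominator (0/0 precision etc.).
UNDEFINED = float("nan")


def f_measure(p: float, r: float) -> float:
    """Harmonic mean of precision and recall: f1 = 2/(1/r + 1/p).

    Undefined (NaN) inputs propagate; a zero precision or recall gives 0.
    """
    if math.isnan(p) or math.isnan(r):
        return UNDEFINED
    if p == 0.0 or r == 0.0:
        return 0.0
    return 2.0 / (1.0 / r + 1.0 / p)


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 truth-by-prediction counts for the binary ablation task."""

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        """Number of evaluated frames."""
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(
            self.tp + other.tp, self.fn + other.fn,
            self.fp + other.fp, self.tn + other.tn,
        )


def confusion(truth, pred) -> ConfusionTable:
    """Exact 2x2 counts from parallel binary label sequences."""
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(pred, dtype=bool)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    return ConfusionTable(
        tp=int((t & p).sum()),
        fn=int((t & ~p).sum()),
        fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()),
    )


def prf(ct: ConfusionTable) -> tuple[float, float, float]:
    """Precision, recall, and F-measure of a confusion table.

    f1 = 2/(1/r + 1/p); any zero denominator yields NaN (undefined), which
    propagates.  A defined-but-zero precision or recall gives f1 = 0.
    """
    p = ct.tp / (ct.tp + ct.fp) if (ct.tp + ct.fp) else UNDEFINED
    r = ct.tp / (ct.tp + ct.fn) if (ct.tp + ct.fn) else UNDEFINED
    return p, r, f_measure(p, r)


def pr_curve(
    truth,
    scores,
    n_thresholds: int = 101,
    gate=None,
) -> list[tuple[float, float, float]]:
    """Precision-recall sweep over an even threshold grid on [0, 1].

    At each threshold tau the prediction is ``score >= tau`` — optionally
    AND-ed with a per-frame boolean ``gate`` (the filtered pipeline's
    arbitration outcome), which is how the filtered methods are swept.
    Points with undefined precision are omitted; recall is non-increasing
    in tau.
    """
    t = np.asarray(truth, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("truth/scores length mismatch")
    if s.size and (s.min() < 0.0 or s.max() > 1.0):
        raise ValueError("scores must lie in [0, 1]")
    g = np.ones_like(t) if gate is None else np.asarray(gate, dtype=bool)
    points = []
    for tau in np.linspace(0.0, 1.0, n_thresholds):
        pred = (s >= tau) & g
        p, r, _ = prf(confusion(t, pred))
        if not math.isnan(p):
            points.append((float(tau), p, r))
    return points


@dataclass
class MetricsReport:
    """Per-sequence and cumulative binary metrics for one method."""

    method: str
    per_sequence: dict[str, tuple[float, float, float]]
    cumulative: ConfusionTable

    @property
    def cumulative_prf(self) -> tuple[float, float, float]:
        return prf(self.cumulative)

    def _mean(self, idx: int) -> float:
        vals = [v[idx] for v in self.per_sequence.values() if not math.isnan(v[idx])]
        return float(np.mean(vals)) if vals else UNDEFINED

    @property
    def mean_precision(self) -> float:
        return self._mean(0)

    @property
    def mean_recall(self) -> float:
        return self._mean(1)

    @property
    def mean_f1(self) -> float:
        return self._mean(2)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "per_sequence": {
                k: {"precision": v[0], "recall": v[1], "f1": v[2]}
                for k, v in self.per_sequence.items()
            },
            "cumulative": {
                "tp": self.cumulative.tp, "fn": self.cumulative.fn,
                "fp": self.cumulative.fp, "tn": self.cumulative.tn,
            },
            "mean": {
                "precision": self.mean_precision,
                "recall": self.mean_recall,
                "f1": self.mean_f1,
            },
        }


@dataclass
class FoldResult:
    """Everything measured on one held-out procedure."""

    validation_id: str
    truth: np.ndarray  # binary ablation ground truth, frame order
    results: list[CompleteResult] = field(default_factory=list)  # CNN methods
    raw_pred: np.ndarray | None = None
    raw_scores: np.ndarray | None = None  # in [0, 1] for PR sweeps
    filtered_pred: np.ndarray | None = None
    timeline: list | None = None


@dataclass
class StudyReport:
    """Cross-validation report: metrics, per-fold results, PR data."""

    metrics: MetricsReport
    folds: list[FoldResult]
    pr_points: list[tuple[float, float, float]]
    seeds: dict

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics.to_dict(),
            "pr_points": [
                {"threshold": t, "precision": p, "recall": r}
                for t, p, r in self.pr_points
            ],
            "seeds": self.seeds,
            "folds": [
                {"validation": f.validation_id, "n_frames": int(len(f.truth))}
                for f in self.folds
            ],
        }


def _fold_seed(seed: int, fold_index: int) -> int:
    return (seed * 1009 + fold_index) % (2**31 - 1)


def cross_validate_cnn(
    ds: AnnotatedDataset,
    splits: SplitPlan,
    backbone_cfg: BackboneConfig = BackboneConfig("small_cnn"),
    train_cfg: TrainConfig = DESK_TRAIN,
    threshold: float = 0.5,
    seed: int = 0,
    rotate: bool = True,
) -> list[FoldResult]:
    """Train one CNN per fold and run both inference passes on the held-out
    procedure.  Each fold's result carries the raw binary predictions, the
    raw positive-class scores, and the filtered (complete-classification)
    predictions, so raw and filtered methods are evaluated from one
    training run."""
    folds: list[FoldResult] = []
    for k, (train_ids, val_id) in enumerate(splits.folds):
        fold_seed = _fold_seed(seed, k)
        train_ds = balanced_subsample(ds.subset(train_ids), seed=fold_seed)
        model = build_model(backbone_cfg, init_seed=fold_seed)
        cfg = TrainConfig(
            iterations=train_cfg.iterations,
            learning_rate=train_cfg.learning_rate,
            batch_size=train_cfg.batch_size,
            seed=fold_seed,
        )
        train(model, train_ds, cfg, rotate=rotate)
        val_frames = ds.subset([val_id]).frames
        truth = np.array([f.label.binary for f in val_frames])
        results = classify_frames(model, val_frames, threshold=threshold)
        raw_scores = np.array([r.ablation_score for r in results])
        fold = FoldResult(
            validation_id=val_id,
            truth=truth,
            results=results,
            raw_pred=raw_scores >= threshold,
            raw_scores=raw_scores,
            filtered_pred=np.array(filter_binary_predictions(results)),
            timeline=segment_timeline(results),
        )
        folds.append(fold)
    return folds


def _svm_folds(
    ds: AnnotatedDataset, splits: SplitPlan, seed: int
) -> list[FoldResult]:
    folds = []
    for k, (train_ids, val_id) in enumerate(splits.folds):
        fold_seed = _fold_seed(seed, k)
        train_ds = balanced_subsample(ds.subset(train_ids), seed=fold_seed)
        labels = [f.label.binary for f in train_ds.frames]
        baseline = SvmBaseline().fit(train_ds.frames, labels)
        val_frames = ds.subset([val_id]).frames
        truth = np.array([f.label.binary for f in val_frames])
        pred, decision = baseline.predict(val_frames)
        # logistic squash of the signed margin -> [0, 1] scores for PR sweeps
        scores = 1.0 / (1.0 + np.exp(-decision))
        folds.append(
            FoldResult(
                validation_id=val_id, truth=truth,
                raw_pred=pred, raw_scores=scores, filtered_pred=pred,
            )
        )
    return folds


def _report(method: str, folds: list[FoldResult], filtered: bool) -> MetricsReport:
    per_seq: dict[str, tuple[float, float, float]] = {}
    cumulative = ConfusionTable()
    for f in folds:
        pred = f.filtered_pred if filtered else f.raw_pred
        ct = confusion(f.truth, pred)
        per_seq[f.validation_id] = prf(ct)
        cumulative = cumulative + ct
    return MetricsReport(method=method, per_sequence=per_seq, cumulative=cumulative)


def evaluate_study(
    ds: AnnotatedDataset,
    splits: SplitPlan,
    method: str,
    backbone_cfg: BackboneConfig = BackboneConfig("small_cnn"),
    train_cfg: TrainConfig = DESK_TRAIN,
    threshold: float = 0.5,
    seed: int = 0,
    folds: list[FoldResult] | None = None,
) -> StudyReport:
    """Evaluate one method (``svm``, ``raw_cnn``, or ``filtered_cnn``) over a
    split plan.

    Per-fold metrics are computed on the complete held-out procedure; the
    cumulative confusion table sums the folds.  Precomputed ``folds`` (from
    :func:`cross_validate_cnn`) may be passed so raw and filtered reports
    share one training run.
    """
    if method not in ("svm", "raw_cnn", "filtered_cnn"):
        raise ValueError(f"unknown method {method!r}")
    if folds is None:
        if method == "svm":
            folds = _svm_folds(ds, splits, seed)
        else:
            folds = cross_validate_cnn(
                ds, splits, backbone_cfg, train_cfg, threshold, seed
            )
    filtered = method == "filtered_cnn"
    metrics = _report(method, folds, filtered=filtered)
    truth = np.concatenate([f.truth for f in folds])
    scores = np.concatenate([f.raw_scores for f in folds])
    gate = np.concatenate([f.filtered_pred for f in folds]) if filtered else None
    points = pr_curve(truth, scores, gate=gate)
    seeds = {
        "seed": seed,
        "threshold": threshold,
        "variant": backbone_cfg.variant,
        "train": {
            "iterations": train_cfg.iterations,
            "learning_rate": train_cfg.learning_rate,
            "batch_size": train_cfg.batch_size,
        },
    }
    return StudyReport(metrics=metrics, folds=folds, pr_points=points, seeds=seeds)
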