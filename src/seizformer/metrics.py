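"""Confusion-matrix metrics, rank-based ROC-AUC, and cross-validation reports.

The positive class is seizure (label 1). Metrics::

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)            (= recall, seizure hit rate)
    specificity = TN / (TN + FP)
    F1          = harmonic mean of precision TP/(TP+FP) and recall

A metric whose denominator is zero is reported as 0.0 with a warning rather
than NaN. AUC uses the tie-corrected Mann-Whitney rank statistic, which
equals the trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import AUCError, ShapeError

METRIC_NAMES = ["accuracy", "sensitivity", "specificity", "f1", "auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(pred, true) -> ConfusionCounts:
    pred = np.asarray(pred, dtype=np.int64).ravel()
    true = np.asarray(true, dtype=np.int64).ravel()
    if pred.shape != true.shape:
        raise ShapeError(f"length mismatch: {pred.shape} vs {true.shape}")
    if not (np.isin(pred, (0, 1)).all() and np.isin(true, (0, 1)).all()):
        raise ShapeError("labels must be 0/1")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (true == 1))),
        fp=int(np.sum((pred == 1) & (true == 0))),
        tn=int(np.sum((pred == 0) & (true == 0))),
        fn=int(np.sum((pred == 0) & (true == 1))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0.0", stacklevel=3)
        return 0.0
    return num / den


def binary_metrics(c: ConfusionCounts) -> dict[str, float]:
    accuracy = _ratio(c.tp + c.tn, c.total, "accuracy")
    sensitivity = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    specificity = _ratio(c.tn, c.tn + c.fp, "specificity")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = sensitivity
    f1 = _ratio(2 * precision * recall, precision + recall, "f1")
    return {"accuracy": accuracy, "sensitivity": sensitivity,
            "specificity": specificity, "f1": f1}


def roc_auc(scores, true) -> float:
    """Tie-corrected Mann-Whitney AUC of positive-class scores."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    true = np.asarray(true, dtype=np.int64).ravel()
    if scores.shape != true.shape:
        raise ShapeError(f"length mismatch: {scores.shape} vs {true.shape}")
    n_pos = int(np.sum(true == 1))
    n_neg = int(np.sum(true == 0))
    if n_pos == 0 or n_neg == 0:
        raise AUCError("AUC needs both classes present")
    ranks = rankdata(scores)            # average ranks handle ties
    r_pos = ranks[true == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class FoldResult:
    """Evaluation of one cross-validation test fold."""

    fold: int
    counts: ConfusionCounts
    metrics: dict[str, float]
    scores: np.ndarray = field(default_factory=lambda: np.array([]))
    true: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class EvalReport:
    """Per-fold metrics plus mean and population std across folds."""

    folds: list[FoldResult]
    mean: dict[str, float]
    std: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Percentages with two decimals, one row per fold + a Mean±std row."""
        rows = []
        for fr in self.folds:
            rows.append({"fold": fr.fold,
                         **{m: round(100 * fr.metrics.get(m, np.nan), 2)
                            for m in METRIC_NAMES}})
        rows.append({"fold": "Mean±std",
                     **{m: f"{100 * self.mean[m]:.2f} ± {100 * self.std[m]:.2f}"
                        for m in METRIC_NAMES}})
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_json(self, path: str | Path) -> None:
        payload = {
            "folds": [{"fold": fr.fold, **fr.metrics,
                       "tp": fr.counts.tp, "fp": fr.counts.fp,
                       "tn": fr.counts.tn, "fn": fr.counts.fn}
                      for fr in self.folds],
            "mean": self.mean,
            "std": self.std,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def aggregate_report(folds: list[FoldResult]) -> EvalReport:
    """Mean and population (÷k) standard deviation per metric across folds."""
    if not folds:
        raise ShapeError("need at least one fold")
    mean: dict[str, float] = {}
    std: dict[str, float] = {}
    for m in METRIC_NAMES:
        vals = np.array([fr.metrics[m] for fr in folds if m in fr.metrics])
        if vals.size == 0:
            continue
        mean[m] = float(vals.mean())
        std[m] = float(vals.std())    # population convention
    return EvalReport(folds=list(folds), mean=mean, std=std)


def evaluate_scores(scores: np.ndarray, true: np.ndarray, fold: int = 0,
                    threshold: float = 0.5) -> FoldResult:
    """Scores + labels -> confusion counts, threshold metrics, and AUC."""
    pred = (np.asarray(scores) >= threshold).astype(np.int64)
    c = confusion_counts(pred, true)
    metrics = binary_metrics(c)
    try:
        metrics["auc"] = roc_auc(scores, true)
    except AUCError:
        warnings.warn("AUC undefined (one class only); omitting", stacklevel=2)
    return FoldResult(fold=fold, counts=c, metrics=metrics,
                      scores=np.asarray(scores), true=np.asarray(true))
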