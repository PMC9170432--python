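"""Segmentation and diagnostic performance metrics.

Per-voxel confusion counts feed sensitivity = TP/(TP+FN), specificity =
TN/(FP+TN) and overall performance = (TP+TN)/(TP+TN+FP+FN); mask overlap is
summarized by the Dice coefficient 2TP/(2TP+FP+FN).  ROC analysis uses the
rank (Mann-Whitney) formulation of the AUC, which equals the probability
that a random positive outscores a random negative with ties counted half.

Metrics undefined by division by zero are reported as NaN with a warning,
never silently zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_from_masks",
    "performance_metrics",
    "dice_coefficient",
    "roc_auc",
    "summarize_counts",
    "metrics_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxelwise 2x2 tally of a binary prediction against truth."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity / specificity / overall performance (+ optional Dice)."""

    sensitivity: float
    specificity: float
    overall_performance: float
    dice: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_from_masks(predicted, truth) -> ConfusionCounts:
    """Per-voxel confusion counts of two congruent binary masks."""
    predicted = np.asarray(predicted).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: {predicted.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(predicted & truth))
    tn = int(np.count_nonzero(~predicted & ~truth))
    fp = int(np.count_nonzero(predicted & ~truth))
    fn = int(np.count_nonzero(~predicted & truth))
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def performance_metrics(c: ConfusionCounts, dice: float | None = None
                        ) -> MetricsReport:
    """Sensitivity, specificity and overall performance from counts.

    An empty positive (or negative) class makes the corresponding ratio
    undefined; it is reported as NaN with a warning rather than 0.
    """
    if c.TP + c.FN > 0:
        sens = c.TP / (c.TP + c.FN)
    else:
        warnings.warn("no positive voxels in truth: sensitivity undefined",
                      stacklevel=2)
        sens = float("nan")
    if c.FP + c.TN > 0:
        spec = c.TN / (c.FP + c.TN)
    else:
        warnings.warn("no negative voxels in truth: specificity undefined",
                      stacklevel=2)
        spec = float("nan")
    overall = (c.TP + c.TN) / c.total
    return MetricsReport(sensitivity=sens, specificity=spec,
                         overall_performance=overall, dice=dice)


def dice_coefficient(predicted, truth) -> float:
    """Dice overlap 2TP / (2TP + FP + FN); two empty masks give 1.0."""
    predicted = np.asarray(predicted).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: {predicted.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(predicted & truth))
    denom = 2 * tp + int(np.count_nonzero(predicted ^ truth))
    if denom == 0:
        warnings.warn("both masks empty: Dice defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * tp / denom


def roc_auc(scores, labels):
    """AUC by the Mann-Whitney rank formulation plus the ROC curve.

    Returns ``(auc, curve)`` where ``curve`` is a DataFrame with columns
    ``threshold, fpr, tpr`` swept over the unique scores.  Ties between a
    positive and a negative score count one half.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC analysis needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = _sk_roc_curve(labels.astype(int), scores,
                                  drop_intermediate=False)
    curve = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return float(auc), curve


def summarize_counts(category_counts: dict) -> dict:
    """Category counts -> percentages of the total, to one decimal place."""
    counts = dict(category_counts)
    if not counts:
        raise ValueError("no categories given")
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be nonnegative")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total count must be positive")
    return {k: round(100.0 * v / total, 1) for k, v in counts.items()}


def metrics_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-image/per-method metric dicts into a tidy DataFrame."""
    return pd.DataFrame(rows)
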