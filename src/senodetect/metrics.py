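"""Classification performance metrics and distribution comparison.

Accuracy, precision, recall and F1 are computed from explicit confusion
counts; ratios with zero denominators are reported as NaN with a flag,
never silently as 0. AUC follows the Mann–Whitney exceedance convention
(ties get half credit). Distribution comparison is the two-sample
Kolmogorov–Smirnov sup-norm ECDF distance D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "classification_metrics",
    "roc_pr",
    "compare_distributions",
    "pearson_r",
    "median_well_metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Flat metrics record; undefined ratios are NaN and listed in flags."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "flags": list(self.flags),
        }


def _check_binary(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values).astype(int)
    bad = set(np.unique(values)) - {0, 1}
    if bad:
        raise ValueError(f"{name} must be binary 0/1; found values {sorted(bad)}")
    return values


def confusion(predicted, truth) -> ConfusionCounts:
    """Confusion counts from aligned binary label vectors."""
    pred = _check_binary(predicted, "predicted")
    true = _check_binary(truth, "truth")
    if len(pred) != len(true):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(true)} truths")
    tp = int(np.sum((pred == 1) & (true == 1)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def classification_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and the harmonic-mean F1.

    F1 is defined as 0 when precision + recall = 0 and both are defined;
    if precision or recall is itself undefined, F1 is flagged undefined.
    """
    if counts.total == 0:
        raise ValueError("all confusion counts are zero; metrics undefined")
    flags: list[str] = []

    accuracy = (counts.tn + counts.tp) / counts.total

    if counts.tp + counts.fp == 0:
        precision, p_def = math.nan, False
        flags.append("precision_undefined")
    else:
        precision, p_def = counts.tp / (counts.tp + counts.fp), True

    if counts.tp + counts.fn == 0:
        recall, r_def = math.nan, False
        flags.append("recall_undefined")
    else:
        recall, r_def = counts.tp / (counts.tp + counts.fn), True

    if not (p_def and r_def):
        f1 = math.nan
        flags.append("f1_undefined")
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)

    return MetricsReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1, flags=tuple(flags)
    )


def roc_pr(scores, truth) -> dict:
    """ROC curve + AUC and precision-recall curve for binary truth."""
    scores = np.asarray(scores, dtype=float)
    true = _check_binary(truth, "truth")
    if len(scores) != len(true):
        raise ValueError("scores and truth must have equal length")
    if len(np.unique(true)) < 2:
        raise ValueError("truth contains a single class; ROC/AUC undefined")
    fpr, tpr, roc_thr = roc_curve(true, scores)
    auc = float(roc_auc_score(true, scores))
    prec, rec, pr_thr = precision_recall_curve(true, scores)
    return {
        "fpr": fpr,
        "tpr": tpr,
        "roc_thresholds": roc_thr,
        "auc": auc,
        "precision": prec,
        "recall": rec,
        "pr_thresholds": pr_thr,
    }


def compare_distributions(sample_a, sample_b) -> float:
    """Two-sample K–S statistic D = sup |ECDF_A − ECDF_B|."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def pearson_r(x, y) -> float:
    """Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    return float(stats.pearsonr(x, y).statistic)


def median_well_metrics(
    table: pd.DataFrame,
    well_col: str = "well",
    pred_col: str = "predicted",
    truth_col: str = "truth",
) -> dict:
    """Per-well metrics, then the median across wells.

    Wells where a ratio is undefined are dropped from that ratio's median.
    """
    per_well: dict[str, list[float]] = {"accuracy": [], "precision": [], "recall": [], "f1": []}
    for _, grp in table.groupby(well_col):
        rep = classification_metrics(confusion(grp[pred_col], grp[truth_col]))
        for key in per_well:
            val = getattr(rep, key)
            if not math.isnan(val):
                per_well[key].append(val)
    return {k: (float(np.median(v)) if v else math.nan) for k, v in per_well.items()}
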