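"""Classifier evaluation: confusion matrices, Se/Sp/precision/F1, ROC/AUC.

Se (sensitivity, recall) = TP/(TP+FN); Sp (specificity) = TN/(TN+FP);
precision = TP/(TP+FP); F1 = 2*precision*recall/(precision+recall).
CTC-positive is the positive class.  A metric with a zero denominator is
reported as undefined (None) rather than 0, so a degenerate test set can
never silently score perfect or zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "confusion",
    "metrics",
    "metrics_report",
    "roc_auc",
    "round_percent",
]

_POSITIVE_TOKENS = {"CTC_POSITIVE", "POSITIVE", "+", "1", "TRUE"}


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/FP/TN counts with CTC-positive as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class Metrics:
    """Fractional metrics in [0, 1]; ``None`` marks an undefined value."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    auc: float | None = None


def _as_positive(label) -> bool:
    if isinstance(label, (bool, np.bool_)):
        return bool(label)
    if isinstance(label, (int, np.integer)):
        return label == 1
    s = getattr(label, "value", label)
    return str(s).upper() in _POSITIVE_TOKENS


def confusion(truth: Sequence, pred: Sequence) -> ConfusionMatrix:
    """Tally a confusion matrix from paired truth/prediction labels."""
    if len(truth) != len(pred):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(pred)} predictions")
    if len(truth) == 0:
        raise ValueError("cannot tally an empty label list")
    t = np.fromiter((_as_positive(x) for x in truth), dtype=bool, count=len(truth))
    p = np.fromiter((_as_positive(x) for x in pred), dtype=bool, count=len(pred))
    return ConfusionMatrix(
        tp=int(np.count_nonzero(t & p)),
        fn=int(np.count_nonzero(t & ~p)),
        fp=int(np.count_nonzero(~t & p)),
        tn=int(np.count_nonzero(~t & ~p)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(cm: ConfusionMatrix, auc: float | None = None) -> Metrics:
    """Sensitivity, specificity, precision and F1 from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("metrics of an all-zero confusion matrix are undefined")
    se = _ratio(cm.tp, cm.tp + cm.fn)
    sp = _ratio(cm.tn, cm.tn + cm.fp)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    if se is None or prec is None or (prec + se) == 0:
        f1 = None
    else:
        f1 = 2.0 * prec * se / (prec + se)
    return Metrics(sensitivity=se, specificity=sp, precision=prec, f1=f1, auc=auc)


def round_percent(fraction: float | None, decimals: int = 1) -> float | None:
    """Percentage rounded half-away-from-zero, matching reported formatting."""
    if fraction is None:
        return None
    scale = 10 ** decimals
    x = fraction * 100.0 * scale
    return math.floor(x + 0.5) / scale if x >= 0 else math.ceil(x - 0.5) / scale


def metrics_report(cm: ConfusionMatrix) -> dict[str, float | None]:
    """One-decimal percentage report of Se/Sp/precision/F1.

    Follows the tabulation convention of the reported results: Se, Sp and
    precision are rounded to one decimal first and the F1 percentage is
    the harmonic mean of the *rounded* sensitivity and precision (the
    published tables are reproducible only under this convention).
    """
    m = metrics(cm)
    se = round_percent(m.sensitivity)
    sp = round_percent(m.specificity)
    prec = round_percent(m.precision)
    if se is None or prec is None or (se + prec) == 0:
        f1 = None
    else:
        f1 = math.floor(2 * se * prec / (se + prec) * 10 + 0.5) / 10
    return {
        "sensitivity_pct": se,
        "specificity_pct": sp,
        "precision_pct": prec,
        "f1_pct": f1,
    }


def roc_auc(scores: Sequence[float], truth: Sequence) -> tuple[list[tuple[float, float]], float]:
    """ROC curve points and AUC via the rank (Mann-Whitney) statistic.

    Ties contribute 1/2.  Curve points are (FPR, TPR) over all score
    thresholds.  Requires both classes present and finite scores.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(truth):
        raise ValueError("scores and truth must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    t = np.fromiter((_as_positive(x) for x in truth), dtype=bool, count=len(truth))
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    ranks = rankdata(scores)
    auc = (ranks[t].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # Curve over all distinct thresholds, descending.
    order = np.argsort(-scores, kind="stable")
    s_sorted, t_sorted = scores[order], t[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    for i in range(len(s_sorted)):
        if t_sorted[i]:
            tp += 1
        else:
            fp += 1
        if i + 1 == len(s_sorted) or s_sorted[i + 1] != s_sorted[i]:
            points.append((fp / n_neg, tp / n_pos))
    return points, float(auc)
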