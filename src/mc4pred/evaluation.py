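"""Confusion counts and the four binary-classification metrics.

Sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
Acc = (TP+TN)/N, and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

A probability is called positive when it is >= the decision threshold.
Any metric whose denominator is zero is defined as 0 (this keeps sweeps
over degenerate thresholds finite).  Reported values are rounded half-up
to 4 decimal places; internal values stay full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np

DEFAULT_THRESHOLD = 0.5
DEFAULT_GRID = tuple(round(0.1 * i, 1) for i in range(1, 10))


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Round half away from zero at ``ndigits`` decimals (0.85625 -> 0.8563)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies of a thresholded prediction against labels."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """Sn/Sp/Acc/MCC at one decision threshold, with the underlying counts."""

    counts: ConfusionCounts
    threshold: float
    Sn: float
    Sp: float
    Acc: float
    MCC: float

    def rounded(self, ndigits: int = 4) -> dict[str, float]:
        return {
            "threshold": self.threshold,
            "Sn": round_half_up(self.Sn, ndigits),
            "Sp": round_half_up(self.Sp, ndigits),
            "Acc": round_half_up(self.Acc, ndigits),
            "MCC": round_half_up(self.MCC, ndigits),
        }


def confusion_at(
    probs: Sequence[float], labels: Sequence[int], threshold: float
) -> ConfusionCounts:
    """Tally the confusion matrix at one threshold (positive iff prob >= t)."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError(f"probs shape {p.shape} != labels shape {y.shape}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def metrics(counts: ConfusionCounts, threshold: float = DEFAULT_THRESHOLD) -> MetricsReport:
    """Compute Sn/Sp/Acc/MCC from confusion counts (zero denominators -> 0)."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    n = counts.total
    if n == 0:
        raise ValueError("cannot compute metrics on an empty evaluation")
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / n
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(counts=counts, threshold=threshold, Sn=sn, Sp=sp, Acc=acc, MCC=mcc)


def evaluate_at(
    probs: Sequence[float], labels: Sequence[int], threshold: float = DEFAULT_THRESHOLD
) -> MetricsReport:
    """Convenience: confusion_at then metrics."""
    return metrics(confusion_at(probs, labels, threshold), threshold)


def threshold_sweep(
    probs: Sequence[float],
    labels: Sequence[int],
    grid: Sequence[float] = DEFAULT_GRID,
) -> list[MetricsReport]:
    """One MetricsReport per threshold, in grid order.

    The grid must be strictly increasing within [0, 1]; the default is
    0.1 to 0.9 in steps of 0.1.
    """
    grid = list(grid)
    if any(not 0.0 <= t <= 1.0 for t in grid):
        raise ValueError("grid thresholds must lie in [0, 1]")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid thresholds must be strictly increasing")
    return [evaluate_at(probs, labels, t) for t in grid]


def mean_report(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of Sn/Sp/Acc/MCC across reports (counts are summed).

    Used to aggregate per-fold cross-validation results; note the metric
    means are NOT the metrics of the summed counts.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    counts = ConfusionCounts(
        TP=sum(r.counts.TP for r in reports),
        TN=sum(r.counts.TN for r in reports),
        FP=sum(r.counts.FP for r in reports),
        FN=sum(r.counts.FN for r in reports),
    )
    k = len(reports)
    return MetricsReport(
        counts=counts,
        threshold=reports[0].threshold,
        Sn=sum(r.Sn for r in reports) / k,
        Sp=sum(r.Sp for r in reports) / k,
        Acc=sum(r.Acc for r in reports) / k,
        MCC=sum(r.MCC for r in reports) / k,
    )
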