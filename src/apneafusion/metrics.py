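"""Confusion-matrix metrics and cross-validation aggregation.

Apnea is the positive class throughout. Per-fold metric sets are
aggregated as unweighted (macro) means with Student-t 95% confidence
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import stats

from .io import APNEA


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with apnea as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricSet:
    """Accuracy, recall, precision, specificity and F1, all in [0, 1].

    ``degenerate`` flags that at least one ratio was 0/0 and reported as 0.
    """

    accuracy: float
    recall: float
    precision: float
    specificity: float
    f1: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name) for f in fields(self) if f.name != "degenerate"
        }


def confusion(predicted: list[str] | np.ndarray, truth: list[str] | np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN from parallel label sequences ('A'/'N')."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError(f"length mismatch: {len(predicted)} predictions, {len(truth)} truths")
    if not predicted:
        raise ValueError("empty label lists")
    p = np.asarray(predicted) == APNEA
    t = np.asarray(truth) == APNEA
    return ConfusionCounts(
        tp=int((p & t).sum()),
        tn=int((~p & ~t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def _ratio(num: int, den: int) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def metric_set(c: ConfusionCounts) -> MetricSet:
    """Accuracy, recall, precision, specificity, F1 from confusion counts.

    0/0 ratios are reported as 0 with the ``degenerate`` flag set.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero counts")
    recall, d1 = _ratio(c.tp, c.tp + c.fn)
    precision, d2 = _ratio(c.tp, c.tp + c.fp)
    specificity, d3 = _ratio(c.tn, c.tn + c.fp)
    if precision + recall > 0:
        f1, d4 = 2 * precision * recall / (precision + recall), False
    else:
        f1, d4 = 0.0, True
    return MetricSet(
        accuracy=(c.tp + c.tn) / c.total,
        recall=recall,
        precision=precision,
        specificity=specificity,
        f1=f1,
        degenerate=d1 or d2 or d3 or d4,
    )


def aggregate_folds(per_fold: list[MetricSet]) -> dict[str, tuple[float, float]]:
    """Per metric: unweighted mean across folds and 95% CI half-width.

    The half-width is ``t_{0.975, k-1} * sd / sqrt(k)``. With a single fold
    the half-width is NaN (mean only).
    """
    if not per_fold:
        raise ValueError("no folds to aggregate")
    out: dict[str, tuple[float, float]] = {}
    k = len(per_fold)
    tq = stats.t.ppf(0.975, k - 1) if k >= 2 else np.nan
    for name in ("accuracy", "recall", "precision", "specificity", "f1"):
        vals = np.array([getattr(m, name) for m in per_fold], dtype=float)
        mean = float(vals.mean())
        half = float(tq * vals.std(ddof=1) / np.sqrt(k)) if k >= 2 else float("nan")
        out[name] = (mean, half)
    return out
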