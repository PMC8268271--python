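"""Classifier evaluation: confusion metrics, threshold sweeps, group tests.

Includes a rate-inversion helper (:func:`counts_from_rates`) that turns a
published (class sizes, sensitivity, specificity) triple back into
integer confusion counts, so printed benchmark tables can be reconciled
against the metric definitions at full precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ThresholdSweep",
    "GroupComparison",
    "metrics",
    "counts_from_rates",
    "optimize_threshold",
    "group_compare",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Percent-scale rates plus the Matthews correlation coefficient.

    Rate metrics whose denominator is zero are ``None``; MCC with a zero
    denominator is 0 by convention.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: float
    ppv: Optional[float]
    npv: Optional[float]
    fdr: Optional[float]
    mcc: float


def metrics(c: ConfusionCounts) -> MetricSet:
    """Standard binary-classification metrics from confusion counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn

    def rate(num: int, den: int) -> Optional[float]:
        return 100.0 * num / den if den > 0 else None

    sens = rate(tp, tp + fn)
    spec = rate(tn, tn + fp)
    ppv = rate(tp, tp + fp)
    npv = rate(tn, tn + fn)
    fdr = None if ppv is None else 100.0 - ppv
    accuracy = 100.0 * (tp + tn) / c.total
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    return MetricSet(
        sensitivity=sens,
        specificity=spec,
        accuracy=accuracy,
        ppv=ppv,
        npv=npv,
        fdr=fdr,
        mcc=mcc,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def counts_from_rates(
    n_pos: int, n_neg: int, sensitivity: float, specificity: float
) -> ConfusionCounts:
    """Invert printed (class sizes, sensitivity, specificity) to counts.

    ``tp = round(sensitivity * n_pos / 100)`` (half-up), ``fn`` the
    remainder, and likewise for ``tn``/``fp``. Warns if the re-derived
    rates differ from the inputs by more than 0.5 percentage points
    (usually a sign the printed rates do not match the class sizes).
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("class sizes must be non-negative")
    for name, r in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not (0.0 <= r <= 100.0):
            raise ValueError(f"{name}={r} outside [0, 100]")
    tp = _round_half_up(sensitivity * n_pos / 100.0)
    tn = _round_half_up(specificity * n_neg / 100.0)
    counts = ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)
    if n_pos > 0 and abs(100.0 * tp / n_pos - sensitivity) > 0.5:
        warnings.warn(
            f"re-derived sensitivity {100.0 * tp / n_pos:.2f} differs from "
            f"input {sensitivity:.2f} by more than 0.5 points",
            stacklevel=2,
        )
    if n_neg > 0 and abs(100.0 * tn / n_neg - specificity) > 0.5:
        warnings.warn(
            f"re-derived specificity {100.0 * tn / n_neg:.2f} differs from "
            f"input {specificity:.2f} by more than 0.5 points",
            stacklevel=2,
        )
    return counts


@dataclass
class ThresholdSweep:
    """Full sweep over candidate thresholds plus the criterion optimum."""

    criterion: str  # "max_mcc" or "max_sens_plus_spec"
    grid: list[float]
    per_threshold: list[tuple[float, MetricSet]]
    best_threshold: float
    best_metrics: MetricSet


def _criterion_value(m: MetricSet, criterion: str) -> float:
    if criterion == "max_mcc":
        return m.mcc
    if criterion == "max_sens_plus_spec":
        return (m.sensitivity or 0.0) + (m.specificity or 0.0)
    raise ValueError(f"unknown criterion {criterion!r}")


def optimize_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    criterion: str = "max_mcc",
) -> ThresholdSweep:
    """Exhaustive threshold sweep over the observed score values.

    Candidates are the sorted unique scores plus one value below the
    minimum (the classify-everything threshold); at each candidate ``t``
    a score ``>= t`` is called positive. Returns the candidate maximizing
    the criterion (smallest threshold on ties) with the full sweep table.
    """
    scores_arr = np.asarray(scores, dtype=float)
    labels_arr = np.asarray(labels, dtype=int)
    if scores_arr.shape != labels_arr.shape or scores_arr.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    n_pos = int(labels_arr.sum())
    n_neg = len(labels_arr) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "threshold optimization needs at least one positive and one "
            f"negative label (got {n_pos} positives, {n_neg} negatives)"
        )
    _criterion_value(metrics(ConfusionCounts(1, 0, 1, 0)), criterion)  # validate name

    uniq = np.unique(scores_arr)
    grid = [float(uniq[0] - 1.0)] + [float(u) for u in uniq]
    per_threshold: list[tuple[float, MetricSet]] = []
    best_t: Optional[float] = None
    best_m: Optional[MetricSet] = None
    best_v = -math.inf
    for t in grid:
        pred = scores_arr >= t
        tp = int(np.sum(pred & (labels_arr == 1)))
        fp = int(np.sum(pred & (labels_arr == 0)))
        fn = n_pos - tp
        tn = n_neg - fp
        m = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        per_threshold.append((t, m))
        v = _criterion_value(m, criterion)
        if v > best_v:  # strict: ties keep the smallest threshold
            best_v, best_t, best_m = v, t, m
    assert best_t is not None and best_m is not None
    return ThresholdSweep(
        criterion=criterion,
        grid=grid,
        per_threshold=per_threshold,
        best_threshold=best_t,
        best_metrics=best_m,
    )


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float


def group_compare(values_a: Sequence[float], values_b: Sequence[float]) -> GroupComparison:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Used to compare flank abs-difference distributions between
    spliceogenic and no-effect variant groups. Two identical
    zero-variance groups return t = 0, p = 1 rather than NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if math.isnan(t):
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:  # zero variance, different means: infinitely separated
            t = math.inf if a.mean() > b.mean() else -math.inf
            p = 0.0
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        t_statistic=float(t),
        p_value=float(p),
    )
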