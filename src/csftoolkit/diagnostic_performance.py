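"""2x2 diagnostic-performance statistics.

Sensitivity, specificity, predictive values (Wilson 95% CIs by default),
likelihood ratios, Youden index, Woolf odds-ratio intervals and Pearson
chi-square tests for a binary marker against a binary reference standard.

A denominator of zero makes the corresponding statistic *undefined*; such
statistics are reported as NaN with their CI bounds NaN, never silently as
zero.  LR+ at perfect specificity is +inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import DomainError

__all__ = [
    "ContingencyTable",
    "ProportionEstimate",
    "DiagnosticPerformance",
    "OddsRatioResult",
    "performance_from_table",
    "table_from_labels",
    "odds_ratio",
    "chi_square_test",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts: marker vs reference.  tp = marker+/reference+, etc."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise DomainError(f"{name} must be a non-negative integer, got {value!r}")
        if self.total == 0:
            raise DomainError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.total

    def swapped_polarity(self) -> "ContingencyTable":
        """Table with marker and reference polarity both inverted; under
        this relabeling Se<->Sp and PPV<->NPV exchange exactly."""
        return ContingencyTable(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=float)


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with its two-sided 95% CI; NaN when undefined."""

    value: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0


@dataclass(frozen=True)
class DiagnosticPerformance:
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    ppv: ProportionEstimate
    npv: ProportionEstimate
    lr_positive: float  # may be +inf; NaN if 0/0
    lr_negative: float
    youden: float
    table: ContingencyTable


def _proportion(numerator: int, denominator: int, ci_method: str) -> ProportionEstimate:
    if denominator == 0:
        return ProportionEstimate(math.nan, math.nan, math.nan, numerator, denominator)
    low, high = proportion_confint(numerator, denominator, alpha=0.05, method=ci_method)
    return ProportionEstimate(numerator / denominator, float(low), float(high),
                              numerator, denominator)


def performance_from_table(
    table: ContingencyTable, ci_method: str = "wilson"
) -> DiagnosticPerformance:
    """Full diagnostic-performance report for one marker/threshold.

    ``ci_method`` is any method accepted by
    :func:`statsmodels.stats.proportion.proportion_confint` ("wilson" by
    default, "beta" for Clopper-Pearson).
    """
    se = _proportion(table.tp, table.tp + table.fn, ci_method)
    sp = _proportion(table.tn, table.tn + table.fp, ci_method)
    ppv = _proportion(table.tp, table.tp + table.fp, ci_method)
    npv = _proportion(table.tn, table.tn + table.fn, ci_method)

    if not (se.defined and sp.defined):
        lr_pos = lr_neg = math.nan
    else:
        fpr = 1.0 - sp.value
        if fpr > 0:
            lr_pos = se.value / fpr
        else:
            lr_pos = math.inf if se.value > 0 else math.nan
        if sp.value > 0:
            lr_neg = (1.0 - se.value) / sp.value
        else:
            lr_neg = math.inf if se.value < 1 else math.nan
    youden = se.value + sp.value - 1.0  # NaN propagates if either undefined
    return DiagnosticPerformance(se, sp, ppv, npv, lr_pos, lr_neg, youden, table)


def table_from_labels(marker: np.ndarray, reference: np.ndarray) -> ContingencyTable:
    """Cross-tabulate per-patient boolean marker and reference arrays."""
    marker = np.asarray(marker, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if marker.shape != reference.shape:
        raise DomainError("marker and reference must have the same length")
    return ContingencyTable(
        tp=int(np.sum(marker & reference)),
        fp=int(np.sum(marker & ~reference)),
        fn=int(np.sum(~marker & reference)),
        tn=int(np.sum(~marker & ~reference)),
    )


@dataclass(frozen=True)
class OddsRatioResult:
    estimate: float  # may be inf/0 with a zero cell and no correction
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane 0.5 continuity correction applied


def odds_ratio(
    table: ContingencyTable, continuity_correction: bool = True
) -> OddsRatioResult:
    """Cross-product odds ratio with the Woolf (log) 95% CI.

    OR = (tp*tn)/(fp*fn); CI = exp(ln OR +/- 1.96*sqrt(1/tp+1/fp+1/fn+1/tn)).
    With a zero cell: if ``continuity_correction`` is true, 0.5 is added to
    every cell (Haldane-Anscombe, flagged in the result); otherwise the
    estimate is +inf or 0 with NaN interval.
    """
    cells = [table.tp, table.fp, table.fn, table.tn]
    if min(cells) == 0:
        if not continuity_correction:
            num, den = table.tp * table.tn, table.fp * table.fn
            est = math.inf if den == 0 else (0.0 if num == 0 else num / den)
            return OddsRatioResult(est, math.nan, math.nan, corrected=False)
        cells = [c + 0.5 for c in cells]
        corrected = True
    else:
        corrected = False
    a, b, c, d = cells
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        est, est * math.exp(-1.96 * se), est * math.exp(1.96 * se), corrected
    )


def chi_square_test(table: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test (1 df) of marker/reference independence.

    Returns (statistic, two-sided p).  Degenerate margins (an expected
    cell of zero) raise a domain error advising an exact test.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DomainError("a margin is zero (expected count 0); use an exact test")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=yates)
    return float(stat), float(p)
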