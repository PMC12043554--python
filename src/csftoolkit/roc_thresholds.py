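"""ROC curves, AUC null tests, Youden-optimal cutoffs and grey zones.

Threshold semantics: a marker calls positive when ``score > c`` (strict),
with candidate thresholds at the unique observed values.  The curve is
anchored at (0,0) (sentinel above the maximum) and (1,1) (sentinel below
the minimum).  The AUC equals both the trapezoidal area under the
(1-specificity, sensitivity) polyline and the Mann-Whitney concordance
probability with ties counted 1/2.

The grey zone is the interval between the Youden-optimal cutoff (lower
bound) and the first threshold at or above it whose positive likelihood
ratio exceeds ``lr_cut`` (upper bound; undefined when no threshold
qualifies).  Marker values at or below the lower bound read "unlikely",
above the upper bound "likely", in between "intermediate".
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DomainError

__all__ = [
    "ROCCurve",
    "GreyZone",
    "build_roc",
    "auc_null_test",
    "youden_optimal_cutoff",
    "grey_zone",
]


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve under the 'score > threshold' rule.

    ``thresholds`` descend from +inf (the (0,0) anchor) through the unique
    observed values to -inf (the (1,1) anchor); ``sensitivities`` and
    ``specificities`` align with them.
    """

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def se_sp_at(self, threshold: float) -> tuple[float, float]:
        idx = int(np.where(self.thresholds == threshold)[0][0])
        return float(self.sensitivities[idx]), float(self.specificities[idx])


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Concordance probability: P(pos > neg) + 0.5*P(tie)."""
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * ties) / (len(pos) * len(neg))


def build_roc(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """Build the empirical ROC curve for a continuous marker.

    ``labels`` are booleans (True = reference positive).  Requires at
    least one positive and one negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise DomainError("scores and labels must have the same length")
    if not (labels.any() and (~labels).any()):
        raise DomainError("need at least one positive and one negative label")
    pos, neg = scores[labels], scores[~labels]
    n_pos, n_neg = len(pos), len(neg)

    uniq_asc, inverse = np.unique(scores, return_inverse=True)
    pos_at = np.bincount(inverse, weights=labels.astype(float), minlength=uniq_asc.size)
    all_at = np.bincount(inverse, minlength=uniq_asc.size).astype(float)
    # counts with score > c, for c at each unique value (descending)
    pos_at_desc = pos_at[::-1]
    all_at_desc = all_at[::-1]
    tp_gt = np.cumsum(pos_at_desc) - pos_at_desc  # strictly greater
    fp_gt = np.cumsum(all_at_desc - pos_at_desc) - (all_at_desc - pos_at_desc)

    thresholds = np.concatenate(([math.inf], uniq_asc[::-1], [-math.inf]))
    se = np.concatenate(([0.0], tp_gt / n_pos, [1.0]))
    sp = np.concatenate(([1.0], 1.0 - fp_gt / n_neg, [0.0]))
    auc = float(np.trapezoid(se, 1.0 - sp))
    return ROCCurve(thresholds, se, sp, auc, int(len(pos)), int(len(neg)))


def _auc_from_ranked(sorted_scores: np.ndarray, pos_idx: tuple[int, ...]) -> float:
    mask = np.zeros(len(sorted_scores), dtype=bool)
    mask[list(pos_idx)] = True
    return _mann_whitney_auc(sorted_scores[mask], sorted_scores[~mask])


def auc_null_test(
    scores: np.ndarray,
    labels: np.ndarray,
    method: str = "auto",
    max_exact: int = 12,
    n_permutations: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Two-sided p-value for the null hypothesis AUC = 0.5.

    ``method``:

    * ``"exact"`` — enumerate every assignment of the positive labels to
      the observed score multiset (C(n, n_pos) placements) and count those
      with |AUC - 0.5| >= observed.  Only feasible for small samples
      (combined n <= ``max_exact``).
    * ``"permutation"`` — seeded Monte-Carlo version of the same test.
    * ``"normal"`` — large-sample normal approximation from the
      Mann-Whitney null variance (tie-corrected).
    * ``"auto"`` — exact when feasible, otherwise normal.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    n_pos, n_neg = len(pos), len(neg)
    if n_pos == 0 or n_neg == 0:
        raise DomainError("need both classes for the AUC null test")
    observed = abs(_mann_whitney_auc(pos, neg) - 0.5)
    n = n_pos + n_neg

    if method == "auto":
        method = "exact" if n <= max_exact else "normal"
    if method == "exact":
        if n > max_exact:
            raise ConfigurationError(
                f"exact enumeration limited to combined n <= {max_exact}; "
                "use method='permutation' or 'normal'"
            )
        hits = total = 0
        for combo in itertools.combinations(range(n), n_pos):
            total += 1
            if abs(_auc_from_ranked(scores, combo) - 0.5) >= observed - 1e-12:
                hits += 1
        return hits / total
    if method == "permutation":
        rng = rng if rng is not None else np.random.default_rng(0)
        perm = labels.copy()
        hits = 0
        for _ in range(n_permutations):
            rng.shuffle(perm)
            if abs(_mann_whitney_auc(scores[perm], scores[~perm]) - 0.5) >= observed - 1e-12:
                hits += 1
        # add-one (include the observed assignment itself)
        return (hits + 1) / (n_permutations + 1)
    if method == "normal":
        # Mann-Whitney U null variance with tie correction
        _, counts = np.unique(scores, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
        var_u = n_pos * n_neg / 12.0 * ((n + 1) - tie_term)
        if var_u <= 0:
            return 1.0
        z = observed * n_pos * n_neg / math.sqrt(var_u)
        return float(2.0 * stats.norm.sf(z))
    raise ConfigurationError(f"unknown method {method!r}")


def youden_optimal_cutoff(curve: ROCCurve) -> tuple[float, float]:
    """Threshold maximizing Youden's J = Se + Sp - 1, with that J.

    Only finite (observed-value) thresholds compete; ties break toward
    the smallest threshold, i.e. the most sensitive cutoff.  A maximum
    J <= 0 (anti-informative marker) is returned with a warning.
    """
    finite = np.isfinite(curve.thresholds)
    j = curve.sensitivities[finite] + curve.specificities[finite] - 1.0
    thresholds = curve.thresholds[finite]
    best_j = j.max()
    # thresholds descend; last argmax is the smallest threshold attaining the max
    best_idx = np.where(j >= best_j - 1e-12)[0][-1]
    if best_j <= 0:
        warnings.warn("marker is non-informative: best Youden J <= 0", stacklevel=2)
    return float(thresholds[best_idx]), float(best_j)


@dataclass(frozen=True)
class GreyZone:
    """Three-way decision interval for a marker."""

    lower: float
    upper: Optional[float]  # None when no threshold reaches LR+ > lr_cut
    lr_cut: float = 10.0

    def __post_init__(self) -> None:
        if self.upper is not None and self.upper < self.lower:
            raise DomainError("grey-zone upper bound below lower bound")

    def classify(self, value: float) -> str:
        """'unlikely' if value <= lower, 'likely' if value > upper, else 'intermediate'."""
        if value <= self.lower:
            return "unlikely"
        if self.upper is not None and value > self.upper:
            return "likely"
        return "intermediate"


def grey_zone(curve: ROCCurve, lr_cut: float = 10.0) -> GreyZone:
    """Derive the grey zone from a ROC curve.

    Lower bound: Youden-optimal cutoff.  Upper bound: the smallest
    threshold at or above the lower bound whose LR+ = Se/(1-Sp) exceeds
    ``lr_cut`` (LR+ is +inf at Sp = 1 provided Se > 0; thresholds with
    Se = 0 are skipped as 0/0-degenerate).  When no threshold qualifies,
    the upper bound is undefined and only unlikely/intermediate labels
    can be emitted.
    """
    lower, _ = youden_optimal_cutoff(curve)
    finite = np.isfinite(curve.thresholds)
    thresholds = curve.thresholds[finite]
    se = curve.sensitivities[finite]
    sp = curve.specificities[finite]
    upper: Optional[float] = None
    # scan from the smallest eligible threshold upward
    for i in range(len(thresholds) - 1, -1, -1):
        c = thresholds[i]
        if c < lower or se[i] == 0:
            continue
        lr = se[i] / (1.0 - sp[i]) if sp[i] < 1 else math.inf
        if lr > lr_cut:
            upper = float(c)
            break
    return GreyZone(lower=lower, upper=upper, lr_cut=lr_cut)
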