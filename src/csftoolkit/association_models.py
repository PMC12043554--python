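"""Univariable screens and backward-stepwise multivariable logistic models.

Continuous risk factors are dichotomized at the cohort median with strict
inequalities ("age < 50 years", "CSF leukocytes > 4/mm3"); boolean fields
pass through unchanged.  Single-factor logistic fits screen candidates;
backward elimination then drops, one at a time, the term with the largest
Wald p-value while it exceeds the exit threshold (default p > 0.05),
refitting after every removal.

Fits are maximum likelihood (statsmodels ``Logit``, Newton/IRLS).  A term
whose coefficient diverges (|beta| > 15, the footprint of complete
separation) is flagged non-converged and reported without trusting its
interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort_io import Cohort
from .errors import ConfigurationError, DomainError

__all__ = [
    "FactorSpec",
    "TermEstimate",
    "LogisticFit",
    "dichotomize",
    "univariable_screen",
    "backward_stepwise",
]

_SEPARATION_BETA = 15.0


@dataclass(frozen=True)
class FactorSpec:
    """How to turn a patient field into a binary risk factor.

    ``direction``: ``below_median`` (indicator value < cohort median),
    ``above_median`` (value > median; the median itself falls in the
    complement class either way) or ``as_is_boolean``.  A fixed
    ``threshold`` replaces the cohort median when given (e.g. the
    pre-registered "age < 50 years" boundary).
    """

    source_field: str
    direction: str = "as_is_boolean"
    label: Optional[str] = None
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.direction not in ("below_median", "above_median", "as_is_boolean"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")

    @property
    def display_label(self) -> str:
        if self.label:
            return self.label
        arrow = {"below_median": "< median", "above_median": "> median", "as_is_boolean": ""}
        return f"{self.source_field} {arrow[self.direction]}".strip()


@dataclass(frozen=True)
class TermEstimate:
    label: str
    coefficient: float
    std_error: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool


@dataclass
class LogisticFit:
    terms: list[TermEstimate]
    intercept: float
    converged: bool
    n_used: int
    removal_trace: list[tuple[str, float]] = field(default_factory=list)

    def term(self, label: str) -> TermEstimate:
        for t in self.terms:
            if t.label == label:
                return t
        raise KeyError(label)


def dichotomize(cohort: Cohort, spec: FactorSpec) -> pd.Series:
    """Per-patient boolean factor values (indexed by patient_id)."""
    frame = cohort.to_frame().set_index("patient_id")
    if spec.source_field not in frame.columns:
        raise ConfigurationError(f"unknown field {spec.source_field!r}")
    col = frame[spec.source_field]
    if spec.direction == "as_is_boolean":
        if not col.dropna().isin([True, False]).all():
            raise ConfigurationError(
                f"{spec.source_field!r} is not boolean; choose a median direction"
            )
        return col.astype("boolean").rename(spec.display_label)
    values = pd.to_numeric(col, errors="coerce")
    if np.nanmin(values) == np.nanmax(values):
        raise DomainError(f"{spec.source_field!r} is constant; factor is degenerate")
    boundary = (
        spec.threshold
        if spec.threshold is not None
        else float(np.nanmedian(values.to_numpy(dtype=float)))
    )
    if spec.direction == "below_median":
        out = values < boundary
    else:
        out = values > boundary
    out[values.isna()] = pd.NA
    return out.astype("boolean").rename(spec.display_label)


def _design(cohort: Cohort, outcome: str, factors: Sequence[FactorSpec]) -> pd.DataFrame:
    frame = cohort.to_frame().set_index("patient_id")
    if outcome not in frame.columns:
        raise ConfigurationError(f"unknown outcome field {outcome!r}")
    data = pd.DataFrame({"__outcome__": frame[outcome].astype(bool)})
    for spec in factors:
        data[spec.display_label] = dichotomize(cohort, spec)
    return data.dropna()  # pairwise-complete over the requested factors


def _fit(data: pd.DataFrame) -> LogisticFit:
    y = data["__outcome__"].astype(float)
    predictors = data.drop(columns="__outcome__").astype(float)
    constant = [c for c in predictors.columns if predictors[c].nunique() < 2]
    if constant:
        raise DomainError(f"degenerate (constant) factor(s): {constant}")
    X = sm.add_constant(predictors, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation emits PerfectSeparation/Runtime warnings
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
            mle_ok = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, method="bfgs")
            mle_ok = False
    terms = []
    all_ok = mle_ok
    for name in X.columns:
        if name == "const":
            continue
        beta = float(res.params[name])
        se = float(res.bse[name])
        ok = mle_ok and abs(beta) <= _SEPARATION_BETA
        all_ok = all_ok and ok
        with np.errstate(over="ignore"):  # separated terms have inf CI bounds
            or_est = float(np.exp(beta))
            ci_low = float(np.exp(beta - 1.96 * se))
            ci_high = float(np.exp(beta + 1.96 * se))
        terms.append(
            TermEstimate(
                label=name,
                coefficient=beta,
                std_error=se,
                odds_ratio=or_est,
                ci_low=ci_low,
                ci_high=ci_high,
                p_value=float(res.pvalues[name]),
                converged=ok,
            )
        )
    return LogisticFit(
        terms=terms,
        intercept=float(res.params["const"]),
        converged=all_ok,
        n_used=int(len(data)),
    )


def univariable_screen(
    cohort: Cohort, outcome: str, factors: Sequence[FactorSpec]
) -> dict[str, LogisticFit]:
    """One single-predictor logistic fit per factor, keyed by label.

    For a binary factor the fitted odds ratio coincides (algebraically)
    with the contingency-table cross-product odds ratio.
    """
    out = {}
    for spec in factors:
        data = _design(cohort, outcome, [spec])
        out[spec.display_label] = _fit(data)
    return out


def backward_stepwise(
    cohort: Cohort,
    outcome: str,
    candidates: Sequence[FactorSpec],
    exit_p: float = 0.05,
) -> LogisticFit:
    """Backward-stepwise elimination on Wald p-values.

    Starts from the full model over ``candidates`` (callers pre-filter
    collinear markers), repeatedly removes the term with the largest
    Wald p while that p exceeds ``exit_p``, refitting after each removal.
    Non-converged (separated) terms are removed first.  Returns the final
    fit with its removal trace; if nothing survives, an intercept-only
    fit is returned.
    """
    data = _design(cohort, outcome, candidates)
    active = [spec.display_label for spec in candidates]
    trace: list[tuple[str, float]] = []
    while active:
        fit = _fit(data[["__outcome__"] + active])
        bad = [t for t in fit.terms if not t.converged]
        if bad:
            worst = max(bad, key=lambda t: abs(t.coefficient))
            trace.append((worst.label, float("nan")))
            active.remove(worst.label)
            continue
        worst = max(fit.terms, key=lambda t: t.p_value)
        if worst.p_value <= exit_p:
            fit.removal_trace = trace
            return fit
        trace.append((worst.label, worst.p_value))
        active.remove(worst.label)
    fit = _fit(data[["__outcome__"]])
    fit.removal_trace = trace
    return fit
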