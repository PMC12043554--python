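import math

import numpy as np
import pytest

from csftoolkit import (
    Cohort,
    FactorSpec,
    GeneratorConfig,
    PatientRecord,
    backward_stepwise,
    dichotomize,
    generate_with_effects,
    odds_ratio,
    table_from_labels,
    univariable_screen,
)
from csftoolkit.errors import ConfigurationError, DomainError


def toy_cohort(ages, leukos=None, isi=None):
    n = len(ages)
    leukos = leukos or [2] * n
    isi = isi if isi is not None else [i % 2 == 0 for i in range(n)]
    return Cohort(
        records=[
            PatientRecord(
                patient_id=f"p{i}", age=a, sex="male", isi_positive=bool(isi[i]),
                cns_ad=False, csf_albumin=200.0, csf_igg=40.0,
                serum_albumin=36.0, serum_igg=11.0, csf_leukocytes=float(leukos[i]),
                hiv_positive=False,
            )
            for i, a in enumerate(ages)
        ]
    )


class TestDichotomize:
    def test_below_median_strict(self):
        cohort = toy_cohort([30, 40, 50, 60, 70])
        out = dichotomize(cohort, FactorSpec("age", "below_median"))
        assert list(out) == [True, True, False, False, False]

    def test_above_median_strict(self):
        cohort = toy_cohort([30, 40, 50], leukos=[1, 4, 9])
        out = dichotomize(cohort, FactorSpec("csf_leukocytes", "above_median"))
        assert list(out) == [False, False, True]

    def test_boolean_passthrough(self):
        cohort = toy_cohort([30, 40, 50], isi=[True, False, True])
        out = dichotomize(cohort, FactorSpec("isi_positive", "as_is_boolean"))
        assert list(out) == [True, False, True]

    def test_fixed_threshold_overrides_median(self):
        cohort = toy_cohort([30, 45, 52, 60, 70])
        out = dichotomize(cohort, FactorSpec("age", "below_median", threshold=50))
        assert list(out) == [True, True, False, False, False]

    def test_constant_field_degenerate(self):
        with pytest.raises(DomainError, match="degenerate"):
            dichotomize(toy_cohort([40, 40, 40]), FactorSpec("age", "below_median"))

    def test_non_boolean_field_as_is_rejected(self):
        with pytest.raises(ConfigurationError):
            dichotomize(toy_cohort([30, 40]), FactorSpec("age", "as_is_boolean"))


class TestUnivariable:
    def test_logistic_or_equals_contingency_or(self, default_cohort):
        spec = FactorSpec("age", "below_median", "age below median")
        fits = univariable_screen(default_cohort, "isi_positive", [spec])
        term = fits["age below median"].terms[0]
        frame = default_cohort.to_frame()
        table = table_from_labels(
            (frame.age < frame.age.median()).to_numpy(), frame.isi_positive.to_numpy()
        )
        assert term.odds_ratio == pytest.approx(
            odds_ratio(table, continuity_correction=False).estimate, rel=1e-6
        )

    def test_intercept_only_closed_form(self, default_cohort):
        fit = backward_stepwise(default_cohort, "isi_positive", [])
        frame = default_cohort.to_frame()
        pi = frame.isi_positive.mean()
        assert fit.intercept == pytest.approx(math.log(pi / (1 - pi)), rel=1e-6)
        assert fit.terms == []

    def test_null_factor_or_near_one(self):
        # outcome independent of the factor at large n
        cohort = generate_with_effects(
            GeneratorConfig(n=4000), intercept=-0.6, coefficients={}, seed=99
        )
        fits = univariable_screen(
            cohort, "isi_positive", [FactorSpec("age", "below_median", "age")]
        )
        term = fits["age"].terms[0]
        assert term.odds_ratio == pytest.approx(1.0, abs=0.25)
        assert term.p_value > 0.05


class TestBackwardStepwise:
    def test_single_significant_candidate_matches_univariable(self, default_cohort):
        spec = FactorSpec("age", "below_median", "age below median")
        uni = univariable_screen(default_cohort, "isi_positive", [spec])
        multi = backward_stepwise(default_cohort, "isi_positive", [spec])
        assert [t.label for t in multi.terms] == ["age below median"]
        assert multi.terms[0].odds_ratio == pytest.approx(
            uni["age below median"].terms[0].odds_ratio, rel=1e-9
        )

    def test_parameter_recovery_on_simulated_effects(self, effects_cohort_factors):
        """True effects: OR 2.5 for age<50 and 14.2 for IgG index>0.7 at
        n=10^4; the final model must retain exactly those two factors and
        estimate each within 15%."""
        cohort, factors = effects_cohort_factors
        fit = backward_stepwise(cohort, "isi_positive", factors)
        labels = sorted(t.label for t in fit.terms)
        assert labels == ["age below 50", "igg index above 0.7"]
        assert fit.term("age below 50").odds_ratio == pytest.approx(2.5, rel=0.15)
        assert fit.term("igg index above 0.7").odds_ratio == pytest.approx(14.2, rel=0.15)

    def test_removal_trace_is_monotone(self, effects_cohort_factors):
        cohort, factors = effects_cohort_factors
        fit = backward_stepwise(cohort, "isi_positive", factors, exit_p=0.05)
        for _, p in fit.removal_trace:
            assert math.isnan(p) or p > 0.05

    def test_all_null_candidates_yield_intercept_only(self):
        """Type-I behavior: one null candidate survives in <= ~5% of runs."""
        kept = 0
        runs = 40
        for seed in range(runs):
            cohort = generate_with_effects(
                GeneratorConfig(n=400), intercept=-0.6, coefficients={}, seed=1000 + seed
            )
            fit = backward_stepwise(
                cohort, "isi_positive", [FactorSpec("age", "below_median", "age")]
            )
            kept += bool(fit.terms)
        assert kept <= 6  # binomial(40, 0.05) upper tail


@pytest.fixture(scope="module")
def effects_cohort_factors():
    cohort = generate_with_effects(
        GeneratorConfig(n=10_000),
        intercept=-1.8,
        coefficients={
            "age_below_50": math.log(2.5),
            "igg_index_above_cutoff": math.log(14.2),
        },
        seed=5,
    )
    frame = cohort.to_frame()
    igg_index = frame.csf_igg * frame.serum_albumin / (frame.csf_albumin * frame.serum_igg)
    factors = [
        FactorSpec("age", "below_median", "age below 50", threshold=50),
        FactorSpec("hiv_positive", "as_is_boolean", "hiv positive"),
        FactorSpec("csf_leukocytes", "above_median", "leukocytes above 4", threshold=4),
        FactorSpec("__igg_index_positive__", "as_is_boolean", "igg index above 0.7"),
    ]

    class WithIndex(Cohort):
        def to_frame(self):
            f = super().to_frame()
            f["__igg_index_positive__"] = (igg_index > 0.7).to_numpy()
            return f

    return WithIndex(records=cohort.records, provenance=cohort.provenance), factors
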