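import math

import numpy as np
import pytest

from csftoolkit import (
    GreyZone,
    auc_null_test,
    build_roc,
    grey_zone,
    youden_optimal_cutoff,
)
from csftoolkit.errors import ConfigurationError, DomainError
from csftoolkit.synthetic_cohort import calibrate_lognormal

PERFECT_SCORES = np.array([0.9, 0.8, 0.6, 0.5, 0.4, 0.3])
PERFECT_LABELS = np.array([1, 1, 1, 0, 0, 0], dtype=bool)

# analytic reference points of the default two-lognormal marker model
# (sigma 0.35/0.30, exceedance 0.57/0.06 at 0.7), from numerically solving
# argmax_c [SF+(c) - SF-(c)] and SF+(c)/SF-(c) = 10 on the exact normal SFs
ANALYTIC_YOUDEN = 0.57755
ANALYTIC_LR10 = 0.70772


def two_lognormal_instance(n, seed, prevalence=0.35):
    rng = np.random.default_rng(seed)
    mu_pos = calibrate_lognormal(0.7, 0.57, 0.35)
    mu_neg = calibrate_lognormal(0.7, 0.06, 0.30)
    labels = rng.random(n) < prevalence
    scores = np.where(
        labels,
        np.exp(rng.normal(mu_pos, 0.35, n)),
        np.exp(rng.normal(mu_neg, 0.30, n)),
    )
    return scores, labels


class TestBuildROC:
    def test_perfect_separation_auc_one(self):
        assert build_roc(PERFECT_SCORES, PERFECT_LABELS).auc == 1.0

    def test_all_tied_scores_auc_half(self):
        curve = build_roc(np.ones(10), np.arange(10) < 4)
        assert curve.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            build_roc(np.array([1.0, 2.0]), np.array([True, True]))

    def test_curve_is_monotone(self, rng):
        scores, labels = two_lognormal_instance(500, 3)
        curve = build_roc(scores, labels)
        assert (np.diff(curve.sensitivities) >= 0).all()
        assert (np.diff(curve.specificities) <= 0).all()
        assert curve.sensitivities[0] == 0 and curve.sensitivities[-1] == 1

    def test_auc_equals_pairwise_concordance(self, rng):
        """Trapezoidal AUC == Mann-Whitney concordance on random instances
        with ties (brute force over all positive-negative pairs)."""
        for _ in range(200):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            curve = build_roc(scores, labels)
            pos, neg = scores[labels], scores[~labels]
            conc = (
                (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
            ) / (len(pos) * len(neg))
            assert curve.auc == pytest.approx(conc, abs=1e-12)

    def test_auc_agrees_with_sklearn(self, rng):
        """Independent cross-check against scikit-learn's rank-based AUC."""
        from sklearn.metrics import roc_auc_score

        for seed in range(20):
            scores, labels = two_lognormal_instance(200, 100 + seed)
            if labels.all() or not labels.any():
                continue
            ours = build_roc(scores, labels).auc
            assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores, labels = two_lognormal_instance(300, 9)
        base = build_roc(scores, labels).auc
        assert build_roc(np.log(scores), labels).auc == pytest.approx(base, abs=1e-12)
        assert build_roc(scores**3, labels).auc == pytest.approx(base, abs=1e-12)


class TestAUCNullTest:
    def test_exact_enumeration_3v3_perfect(self):
        # 2 of C(6,3)=20 label placements reach |AUC-0.5| = 0.5
        p = auc_null_test(PERFECT_SCORES, PERFECT_LABELS, method="exact")
        assert p == pytest.approx(0.1)

    def test_auc_half_gives_p_one(self):
        scores = np.array([1.0, 1.0, 1.0, 1.0])
        labels = np.array([True, True, False, False])
        assert auc_null_test(scores, labels, method="exact") == pytest.approx(1.0)

    def test_exact_beyond_bound_is_configuration_error(self):
        scores, labels = two_lognormal_instance(40, 5)
        with pytest.raises(ConfigurationError):
            auc_null_test(scores, labels, method="exact")

    def test_monte_carlo_converges_to_exact(self):
        rng = np.random.default_rng(77)
        p_mc = auc_null_test(
            PERFECT_SCORES, PERFECT_LABELS, method="permutation",
            n_permutations=20_000, rng=rng,
        )
        se = math.sqrt(0.1 * 0.9 / 20_000)
        assert abs(p_mc - 0.1) < 3 * se

    def test_normal_approximation_detects_separation(self):
        scores, labels = two_lognormal_instance(400, 21)
        assert auc_null_test(scores, labels, method="normal") < 1e-6


class TestYouden:
    def test_perfect_separation_cutoff(self):
        curve = build_roc(PERFECT_SCORES, PERFECT_LABELS)
        cutoff, j = youden_optimal_cutoff(curve)
        assert cutoff == 0.5 and j == 1.0

    @pytest.mark.filterwarnings("ignore:marker is non-informative")
    def test_equals_exhaustive_scan(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            curve = build_roc(scores, labels)
            _, best_j = youden_optimal_cutoff(curve)
            pos, neg = scores[labels], scores[~labels]
            brute = max(
                np.mean(pos > c) + np.mean(neg <= c) - 1 for c in np.unique(scores)
            )
            assert best_j == pytest.approx(brute, abs=1e-12)

    def test_anti_informative_marker_warns(self):
        with pytest.warns(UserWarning, match="non-informative"):
            _, j = youden_optimal_cutoff(build_roc(PERFECT_SCORES, ~PERFECT_LABELS))
        assert j <= 0


class TestGreyZone:
    def test_recovers_analytic_bounds_on_calibrated_synthetic(self):
        scores, labels = two_lognormal_instance(100_000, 42)
        curve = build_roc(scores, labels)
        zone = grey_zone(curve)
        assert zone.lower == pytest.approx(ANALYTIC_YOUDEN, abs=0.05)
        assert zone.upper == pytest.approx(ANALYTIC_LR10, abs=0.01)

    def test_perfect_classifier_degenerate_zone(self):
        zone = grey_zone(build_roc(PERFECT_SCORES, PERFECT_LABELS))
        assert zone.lower == zone.upper == 0.5

    @pytest.mark.filterwarnings("ignore:marker is non-informative")
    def test_upper_undefined_when_lr_never_reached(self):
        # identically distributed classes: LR+ = 1 at every threshold
        scores = np.tile([1.0, 2.0, 3.0], 20)
        labels = np.tile([True, True, True, False, False, False], 10)
        zone = grey_zone(build_roc(scores, labels), lr_cut=10)
        assert zone.upper is None
        assert zone.classify(1e9) == "intermediate"

    @pytest.mark.filterwarnings("ignore:marker is non-informative")
    def test_lower_never_exceeds_upper(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 80))
            scores = rng.normal(size=n) + rng.random(n)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            zone = grey_zone(build_roc(scores, labels))
            if zone.upper is not None:
                assert zone.lower <= zone.upper

    def test_classification_intervals(self):
        zone = GreyZone(lower=0.67, upper=0.80)
        assert zone.classify(0.63) == "unlikely"
        assert zone.classify(0.67) == "unlikely"  # boundary belongs below
        assert zone.classify(0.70) == "intermediate"
        assert zone.classify(0.80) == "intermediate"
        assert zone.classify(0.85) == "likely"

    def test_invalid_bounds_rejected(self):
        with pytest.raises(DomainError):
            GreyZone(lower=0.8, upper=0.7)
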