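"""Statistical evaluation: Mann-Whitney, ROC/DeLong, confusion metrics, Spearman."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from ctmeth.core_model import InputError
from ctmeth.evaluation import (
    confusion_metrics,
    evaluate_cohort,
    mann_whitney_test,
    roc_auc,
    spearman_concordance,
    summarize_trajectory,
)


def brute_force_auc(cases, controls):
    """Concordant-pair fraction with ties counted one half."""
    wins = sum(
        1.0 if x > y else 0.5 if x == y else 0.0
        for x, y in itertools.product(cases, controls)
    )
    return wins / (len(cases) * len(controls))


class TestMannWhitney:
    def test_exact_enumeration_of_fully_separated_triples(self):
        res = mann_whitney_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.u == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_tied_groups_give_p_one(self):
        res = mann_whitney_test([5, 5], [5, 5])
        assert res.p_value == 1.0

    def test_average_rank_ties_in_u(self):
        assert mann_whitney_test([1, 2], [1, 2]).u == pytest.approx(2.0)

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            mann_whitney_test([], [1.0])

    @given(st.integers(min_value=0, max_value=500))
    def test_exact_path_matches_scipy_exact(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        a, b = rng.normal(size=n1), rng.normal(size=n2)
        ours = mann_whitney_test(a, b)
        ref = sps.mannwhitneyu(a, b, method="exact", alternative="two-sided")
        assert ours.method == "exact"
        assert ours.u == pytest.approx(float(ref.statistic))
        assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    @given(st.integers(min_value=0, max_value=200))
    def test_asymptotic_path_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        a = np.round(rng.normal(size=15), 1)  # rounding induces ties
        b = np.round(rng.normal(0.4, 1.0, size=12), 1)
        ours = mann_whitney_test(a, b)
        ref = sps.mannwhitneyu(a, b, method="asymptotic", alternative="two-sided")
        assert ours.method == "asymptotic"
        assert ours.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_method_switch_at_pooled_size_boundary(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=6), rng.normal(size=6)  # pooled 12 -> exact
        assert mann_whitney_test(a, b).method == "exact"
        a, b = rng.normal(size=7), rng.normal(size=6)  # pooled 13 -> asymptotic
        assert mann_whitney_test(a, b).method == "asymptotic"


class TestRocAuc:
    def test_three_of_four_pairs_concordant(self):
        res = roc_auc([3, 1, 2, 0], [True, True, False, False])
        assert res.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        res = roc_auc([10, 9, 1, 2], [True, True, False, False])
        assert res.auc == 1.0

    def test_single_tied_pair_scores_half(self):
        assert roc_auc([5, 5], [True, False]).auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_auc([1, 2], [True, True])

    @given(st.integers(min_value=0, max_value=300))
    def test_auc_equals_brute_force_and_u_statistic_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        m, n = int(rng.integers(2, 11)), int(rng.integers(2, 11))
        cases = np.round(rng.normal(1.0, 1.0, size=m), 1)
        controls = np.round(rng.normal(0.0, 1.0, size=n), 1)
        scores = np.concatenate([cases, controls])
        labels = np.array([True] * m + [False] * n)
        auc = roc_auc(scores, labels).auc
        assert auc == pytest.approx(brute_force_auc(cases, controls), abs=1e-12)
        u = mann_whitney_test(cases, controls).u
        assert auc == pytest.approx(u / (m * n), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_best_threshold_maximizes_youden(self):
        scores = [0.0, 10.0, 20.0, 30.0, 40.0, 50.0]
        labels = [False, False, False, True, True, True]
        res = roc_auc(scores, labels)
        assert 20.0 < res.best_threshold < 30.0
        # calling positive above the chosen threshold separates perfectly
        cf = confusion_metrics(scores, labels, res.best_threshold)
        assert cf.sensitivity == 1.0 and cf.specificity == 1.0

    def test_delong_interval_contains_auc_and_stays_in_unit_range(self):
        rng = np.random.default_rng(5)
        scores = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 30)])
        labels = np.array([True] * 30 + [False] * 30)
        res = roc_auc(scores, labels)
        lo, hi = res.auc_ci
        assert 0.0 <= lo <= res.auc <= hi <= 1.0


class TestConfusionMetrics:
    def test_worked_counts(self):
        # 8 cases above, 2 below; 9 controls below, 1 above
        scores = [50] * 8 + [10] * 2 + [10] * 9 + [50] * 1
        labels = [True] * 10 + [False] * 10
        cf = confusion_metrics(scores, labels, threshold=38.5)
        assert (cf.tp, cf.fn, cf.tn, cf.fp) == (8, 2, 9, 1)
        assert cf.sensitivity == pytest.approx(0.80)
        assert cf.specificity == pytest.approx(0.90)
        assert cf.accuracy == pytest.approx(0.85)
        assert cf.positive_likelihood_ratio == pytest.approx(8.0)

    def test_perfect_classifier_has_undefined_lr(self):
        cf = confusion_metrics([50, 60, 10, 20], [True, True, False, False], 38.5)
        assert cf.sensitivity == 1.0 and cf.specificity == 1.0
        assert cf.positive_likelihood_ratio is None

    def test_score_exactly_on_threshold_is_a_negative_call(self):
        cf = confusion_metrics([38.5, 50.0], [True, True], 38.5)
        assert (cf.tp, cf.fn) == (1, 1)

    def test_wilson_intervals_match_statsmodels_reference(self):
        from statsmodels.stats.proportion import proportion_confint

        cf = confusion_metrics(
            [50] * 8 + [10] * 2 + [10] * 9 + [50], [True] * 10 + [False] * 10, 38.5
        )
        lo, hi = proportion_confint(8, 10, method="wilson")
        assert cf.sensitivity_ci == pytest.approx((lo, hi))

    @given(st.integers(min_value=0, max_value=100))
    def test_invariance_under_joint_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = rng.random(20) < 0.5
        if labels.all() or not labels.any():
            labels[0] = True
            labels[1] = False
        thr = float(rng.normal())
        a = confusion_metrics(scores, labels, thr)
        b = confusion_metrics(np.exp(scores), labels, np.exp(thr))
        assert (a.tp, a.fn, a.tn, a.fp) == (b.tp, b.fn, b.tn, b.fp)

    def test_wilson_sensitivity_coverage_near_nominal(self):
        """Wilson 95% CI for sensitivity at n=40 covers the truth ~95% of the time."""
        rng = np.random.default_rng(7)
        true_sens, n, covered, sims = 0.83, 40, 0, 2000
        for _ in range(sims):
            tp = rng.binomial(n, true_sens)
            scores = [50.0] * tp + [10.0] * (n - tp) + [10.0, 10.0]
            labels = [True] * n + [False, False]
            lo, hi = confusion_metrics(scores, labels, 38.5).sensitivity_ci
            covered += lo <= true_sens <= hi
        rate = covered / sims
        se = np.sqrt(0.95 * 0.05 / sims)
        assert abs(rate - 0.95) <= 2 * se + 0.01


class TestSpearman:
    def test_monotone_and_antitone_extremes(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman_concordance(x, [v**3 for v in x])[0] == pytest.approx(1.0)
        assert spearman_concordance(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_hand_rank_value(self):
        rho, _ = spearman_concordance([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_mismatched_or_tiny_inputs_rejected(self):
        with pytest.raises(InputError):
            spearman_concordance([1, 2, 3], [1, 2])
        with pytest.raises(InputError):
            spearman_concordance([1, 2], [1, 2])


class TestEvaluateCohort:
    def test_fully_separated_cohort(self):
        cm = [100.0, 90.0, 80.0, 0.0, 0.0, 5.0]
        labels = ["cancer", "cancer", "cancer", "benign", "normal", "normal"]
        rep = evaluate_cohort(cm, labels, threshold=38.5)
        assert rep.roc.auc == 1.0
        assert rep.confusion.accuracy == 1.0
        assert rep.n_control == 3  # benign and normal pooled

    def test_training_mode_derives_youden_threshold(self):
        cm = [100.0, 90.0, 80.0, 0.0, 0.0, 5.0]
        labels = ["cancer"] * 3 + ["benign", "normal", "normal"]
        rep = evaluate_cohort(cm, labels, threshold="derive")
        assert rep.threshold_derived
        cf = confusion_metrics(cm, [l == "cancer" for l in labels], rep.threshold)
        assert cf.sensitivity + cf.specificity == 2.0

    def test_permuted_labels_give_null_auc(self):
        rng = np.random.default_rng(3)
        cm = rng.lognormal(3, 1, size=40)
        aucs = []
        for _ in range(400):
            labels = np.array(["cancer"] * 20 + ["normal"] * 20)
            rng.shuffle(labels)
            aucs.append(evaluate_cohort(cm, labels, threshold=38.5).roc.auc)
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) <= 3 * se

    def test_unknown_labels_rejected(self):
        with pytest.raises(InputError):
            evaluate_cohort([1.0, 2.0, 3.0, 4.0], ["cancer", "cancer", "bad", "normal"])


class TestTrajectory:
    def test_falling_series_deltas_and_directions(self):
        ts = summarize_trajectory("p1", [(0, 400.0), (21, 100.0), (42, 50.0)])
        assert ts.delta_from_baseline == (0.0, -300.0, -350.0)
        assert ts.directions == ("fall", "fall")

    def test_constant_series_is_flat(self):
        ts = summarize_trajectory("p1", [(0, 60.0), (21, 60.0)])
        assert ts.directions == ("flat",)

    def test_small_change_within_tolerance_is_flat(self):
        ts = summarize_trajectory("p1", [(0, 10.0), (21, 10.5)], flat_tolerance=1.0)
        assert ts.directions == ("flat",)

    def test_points_sorted_by_day_and_single_draw_rejected(self):
        ts = summarize_trajectory("p1", [(21, 100.0), (0, 400.0)])
        assert ts.days == (0, 21)
        assert ts.baseline_cm == 400.0
        with pytest.raises(InputError):
            summarize_trajectory("p1", [(0, 1.0)])
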