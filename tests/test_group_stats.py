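"""Group tests, ROC/Youden, DeLong comparison, logistic combination."""

import numpy as np
import pytest
from scipy import stats

from ctrwdwi.group_stats import (
    auc_mann_whitney,
    compare_groups,
    delong_compare,
    logistic_combine,
    report_to_tables,
    roc_analysis,
    run_study_analysis,
)
from ctrwdwi.synthetic_data import generate_cohort


class TestCompareGroups:
    def test_exact_mann_whitney_on_disjoint_triples(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = compare_groups(values, labels, test="mann-whitney")
        assert res.test == "mann-whitney"
        # U = 0; exact two-sided p = 2 * 1/C(6,3) = 0.1
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_gate_picks_t_test_for_gaussian_groups(self, rng):
        g0 = rng.normal(0.0, 1.0, 40)
        g1 = rng.normal(0.5, 1.0, 40)
        res = compare_groups(np.concatenate([g0, g1]), np.repeat([0, 1], 40))
        if res.normal:
            assert res.test == "t-test"
            expected = stats.ttest_ind(g0, g1, equal_var=True).pvalue
        else:
            expected = stats.mannwhitneyu(g0, g1, alternative="two-sided").pvalue
        assert res.p_value == pytest.approx(expected, rel=1e-12)

    def test_gate_picks_mann_whitney_for_skewed_groups(self, rng):
        g0 = rng.lognormal(0.0, 1.0, 50)
        g1 = rng.lognormal(0.8, 1.0, 50)
        res = compare_groups(np.concatenate([g0, g1]), np.repeat([0, 1], 50))
        assert res.test == "mann-whitney"
        assert "(" in res.summary_neg  # median (IQR) formatting

    def test_location_shift_leaves_decision_and_p_unchanged(self, rng):
        v = rng.lognormal(0.0, 0.6, 60)
        labels = np.repeat([0, 1], 30)
        base = compare_groups(v, labels)
        shifted = compare_groups(v + 137.0, labels)
        assert base.test == shifted.test
        assert base.p_value == pytest.approx(shifted.p_value, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(np.arange(5.0), np.array([0, 0, 1, 1, 1]))

    def test_label_shuffled_halves_of_one_sample_are_not_significant_at_floor(
        self, rng
    ):
        v = rng.normal(0, 1, 40)
        labels = rng.permutation(np.repeat([0, 1], 20))
        res = compare_groups(v, labels)
        assert res.p_value > 1e-4


class TestRocAnalysis:
    def test_perfect_separation(self):
        res = roc_analysis([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1], positive_high=True)
        assert res.auc == 1.0
        assert res.sensitivity == res.specificity == res.accuracy == 100.0
        assert 2.0 < res.cutoff < 3.0

    def test_chance_level_interleaving(self):
        res = roc_analysis([3.0, 1.0, 2.0, 4.0], [0, 1, 0, 1])
        assert res.auc == pytest.approx(0.5)

    def test_orientation_flip_mirrors_auc(self, rng):
        scores = rng.normal(0, 1, 40)
        labels = rng.integers(0, 2, 40).astype(bool)
        labels[:2] = [True, False]
        hi = roc_analysis(scores, labels, positive_high=True)
        lo = roc_analysis(scores, labels, positive_high=False)
        assert hi.auc == pytest.approx(1.0 - lo.auc, abs=1e-12)

    def test_auc_equals_tie_corrected_mann_whitney_u(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 60))
            scores = np.round(rng.normal(0, 1, n), 1)  # rounding induces ties
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            u = stats.mannwhitneyu(
                scores[labels], scores[~labels], alternative="two-sided"
            ).statistic
            expected = u / (labels.sum() * (~labels).sum())
            assert auc_mann_whitney(scores, labels) == pytest.approx(expected, abs=1e-12)
            assert roc_analysis(scores, labels).auc == pytest.approx(expected, abs=1e-12)

    def test_youden_point_beats_every_threshold_exhaustively(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 80))
            scores = np.round(rng.normal(0, 1, n), 1)
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            res = roc_analysis(scores, labels, positive_high=True)
            best_j = res.sensitivity / 100 + res.specificity / 100 - 1.0
            for thr in np.concatenate([scores - 1e-9, scores + 1e-9]):
                sens = (scores[labels] >= thr).mean()
                spec = (scores[~labels] < thr).mean()
                assert sens + spec - 1.0 <= best_j + 1e-9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], [1, 1])


class TestDelong:
    def test_identical_scores_degenerate(self, rng):
        s = rng.normal(0, 1, 30)
        y = rng.integers(0, 2, 30).astype(bool)
        y[:2] = [True, False]
        res = delong_compare(s, s, y)
        assert res.degenerate and res.p_value == 1.0 and res.auc_difference == 0.0

    def test_monotone_transform_preserves_auc(self, rng):
        s = rng.normal(0, 1, 40)
        y = rng.integers(0, 2, 40).astype(bool)
        y[:2] = [True, False]
        res = delong_compare(s, np.exp(s), y)
        assert res.auc_difference == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_frozen_cross_check_against_r_proc(self):
        # expected values computed independently with R pROC
        # (roc(direction=">"), roc.test(method="delong"), ci.auc(method="delong"))
        y = np.array([0] * 12 + [1] * 18, bool)
        a = np.array([0.9, 1.2, 1.05, 1.3, 1.1, 0.95, 1.25, 1.4, 1.0, 1.15, 1.35,
                      1.22, 0.7, 0.85, 0.9, 0.6, 1.0, 0.75, 0.8, 0.95, 0.65, 0.88,
                      0.92, 0.7, 1.05, 0.78, 0.83, 0.6, 0.97, 0.74])
        b = np.array([1.5, 1.8, 1.6, 2.0, 1.7, 1.4, 1.9, 2.1, 1.55, 1.75, 2.05,
                      1.85, 1.2, 1.5, 1.45, 1.0, 1.65, 1.3, 1.35, 1.5, 1.1, 1.42,
                      1.48, 1.15, 1.7, 1.28, 1.38, 1.05, 1.58, 1.22])
        ra = roc_analysis(a, y, positive_high=False)
        rb = roc_analysis(b, y, positive_high=False)
        assert ra.auc == pytest.approx(0.949074074074074, abs=1e-12)
        assert rb.auc == pytest.approx(0.918981481481482, abs=1e-12)
        assert ra.ci_low == pytest.approx(0.879670442194817, abs=1e-12)
        assert ra.ci_high == 1.0
        res = delong_compare(-a, -b, y)
        assert res.p_value == pytest.approx(0.247611244050800, abs=1e-12)


class TestLogisticCombine:
    def test_single_feature_score_is_monotone_in_the_feature(self, rng):
        x = rng.normal(0, 1, 60)
        y = (x + rng.normal(0, 1, 60) > 0).astype(int)
        res = logistic_combine({"x": x}, y)
        combined = roc_analysis(res.combined_score, y, positive_high=True)
        raw = roc_analysis(x, y, positive_high=True)
        assert combined.auc == pytest.approx(raw.auc, abs=1e-12)

    def test_duplicate_feature_is_dropped_and_score_unchanged(self, rng):
        x = rng.normal(0, 1, 80)
        y = (x + rng.normal(0, 1, 80) > 0).astype(int)
        single = logistic_combine({"x": x}, y)
        dup = logistic_combine({"x": x, "x_copy": x}, y)
        assert dup.collinear_dropped == ["x_copy"]
        assert np.allclose(dup.combined_score, single.combined_score, atol=1e-6)

    def test_perfect_separation_is_flagged_but_scored(self):
        x = np.concatenate([np.zeros(10), np.ones(10)]) + np.arange(20) * 1e-4
        y = np.repeat([0, 1], 10)
        res = logistic_combine({"x": x}, y)
        assert res.separation_flag
        assert roc_analysis(res.combined_score, y).auc == 1.0

    def test_null_features_rarely_selected(self, rng):
        hits = 0
        for i in range(60):
            x = rng.normal(0, 1, 81)
            y = rng.permutation(np.repeat([0, 1], [15, 66]))
            res = logistic_combine({"x": x}, y)
            hits += res.univariate_p["x"] < 0.05
        assert hits <= 10  # ~5% of 60 with slack

    def test_too_few_lesions_rejected(self):
        with pytest.raises(ValueError):
            logistic_combine({"x": np.arange(5.0)}, np.array([0, 1, 0, 1, 0]))


class TestStudyAnalysis:
    def test_report_structure_on_default_cohort(self):
        cohort = generate_cohort(seed=4)
        report = run_study_analysis(cohort)
        assert set(report) == {"grade", "variant"}
        for contrast, entry in report.items():
            assert set(entry["parameters"]) == {"adc", "d", "alpha", "beta"}
            for block in entry["parameters"].values():
                assert 0.0 <= block["roc"]["auc"] <= 1.0
                assert 0.0 <= block["comparison"]["p_value"] <= 1.0
            assert entry["combined"]["roc"]["auc"] >= 0.5
        comp, perf = report_to_tables(report)
        assert len(comp) == 8
        assert len(perf) == 10

    def test_constant_parameter_is_uninformative(self):
        cohort = generate_cohort(seed=5)
        cohort["alpha"] = 0.85
        report = run_study_analysis(cohort, contrasts=("grade",))
        block = report["grade"]["parameters"]["alpha"]
        assert block["comparison"]["p_value"] == pytest.approx(1.0, abs=1e-9)
        assert block["roc"]["auc"] == pytest.approx(0.5, abs=1e-12)

    def test_missing_label_column_is_configuration_error(self):
        cohort = generate_cohort(seed=6).drop(columns=["variant"])
        with pytest.raises(ValueError):
            run_study_analysis(cohort, contrasts=("variant",))
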