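"""Cohort statistics: oracles, published-count checks and identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dectpeel import (
    CohortSpec,
    TwoByTwo,
    chi_square_2x2,
    cohen_kappa,
    cohort_report,
    compare_auc,
    generate_cohort,
    icc,
    logistic_fit,
    mann_whitney,
    odds_ratio,
    roc_auc,
)
from dectpeel.errors import (
    DegenerateDataError,
    UndefinedOddsRatioError,
    ValidationError,
)

# qualitative reader calls as published counts:
# peritumoral enhancement 9/14 MVI+ vs 8/22 MVI-; non-smooth margin 10/14 vs 10/22
ENHANCEMENT = TwoByTwo(a=9, b=5, c=8, d=14)
MARGIN = TwoByTwo(a=10, b=4, c=10, d=12)


def binary_scores(pos_flagged, n_pos, neg_flagged, n_neg):
    scores = np.r_[np.repeat([1.0, 0.0], [pos_flagged, n_pos - pos_flagged]),
                   np.repeat([1.0, 0.0], [neg_flagged, n_neg - neg_flagged])]
    labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
    return scores, labels


class TestMannWhitney:
    def test_fully_tied_groups(self):
        u, p = mann_whitney([5.0] * 4, [5.0] * 6)
        assert u == pytest.approx(12.0)  # n_a*n_b/2
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_of_separated_groups(self):
        # all 20 orderings of 3+3: the observed extreme has two-sided p = 2/20
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_power_at_reported_group_parameters(self):
        # 0.07+/-0.03 vs 0.10+/-0.03 at n=22/14 is a ~1 SD shift: the test
        # should reject at alpha=0.05 in well over half the replicates
        rng = np.random.default_rng(12)
        spec = CohortSpec(features={"f": (0.07, 0.03, 0.10, 0.03)})
        hits = 0
        reps = 200
        for _ in range(reps):
            t = generate_cohort(spec, rng=rng)
            _, p = mann_whitney(t.loc[t.mvi == 0, "f"], t.loc[t.mvi == 1, "f"])
            hits += p < 0.05
        assert hits / reps > 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestChiSquare:
    def test_published_enhancement_table(self):
        stat, p = chi_square_2x2(ENHANCEMENT)
        assert p == pytest.approx(0.10, abs=0.005)

    def test_published_margin_table(self):
        _, p = chi_square_2x2(MARGIN)
        assert p == pytest.approx(0.13, abs=0.005)

    def test_balanced_table_is_null(self):
        stat, p = chi_square_2x2(TwoByTwo(5, 5, 5, 5))
        assert stat == 0.0 and p == pytest.approx(1.0)


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_published_binary_feature_aucs(self):
        r1 = roc_auc(*binary_scores(9, 14, 8, 22))
        assert r1.auc == pytest.approx(0.64, abs=0.005)
        r2 = roc_auc(*binary_scores(10, 14, 10, 22))
        assert r2.auc == pytest.approx(0.63, abs=0.005)

    def test_binary_predictor_auc_is_mean_of_sens_spec(self):
        r = roc_auc(*binary_scores(9, 14, 8, 22))
        assert r.auc == pytest.approx((r.sensitivity + r.specificity) / 2)

    def test_label_permutation_gives_chance_auc(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, size=4000)
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_ci_contains_auc(self):
        rng = np.random.default_rng(2)
        r = roc_auc(rng.normal(size=40) + np.r_[np.zeros(20), np.ones(20)],
                    np.r_[np.zeros(20, int), np.ones(20, int)])
        assert r.ci_low <= r.auc <= r.ci_high

    def test_missing_scores_dropped_pairwise(self):
        scores = [np.nan, 1, 2, 3, 4, 5]
        labels = [1, 0, 0, 0, 1, 1]
        r = roc_auc(scores, labels)
        assert r.n_pos == 2 and r.n_neg == 3

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2, 3], [1, 1, 1])

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.integers(0, 5), min_size=2, max_size=12),
           st.lists(st.integers(0, 5), min_size=2, max_size=12))
    def test_auc_equals_trapezoidal_integration(self, neg, pos):
        # tie half-credit U-statistic vs independent trapezoid oracle
        from sklearn.metrics import roc_curve

        scores = np.r_[neg, pos].astype(float)
        labels = np.r_[np.zeros(len(neg), int), np.ones(len(pos), int)]
        fpr, tpr, _ = roc_curve(labels, scores)
        trapezoid = float(np.trapezoid(tpr, fpr))
        assert roc_auc(scores, labels).auc == pytest.approx(trapezoid, abs=1e-12)


class TestCompareAuc:
    def test_identical_scores(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=30)
        labels = np.r_[np.zeros(15, int), np.ones(15, int)]
        delta, p = compare_auc(s, s, labels)
        assert delta == 0.0 and p == 1.0

    def test_monotone_transform_changes_nothing(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        labels = rng.permutation(np.r_[np.zeros(20, int), np.ones(20, int)])
        delta, _ = compare_auc(s, np.exp(2 * s) + 3, labels)
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_type_one_error_near_nominal_under_null(self):
        # correlated scores with identical population AUC
        rng = np.random.default_rng(7)
        reps, hits = 400, 0
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        shift = np.r_[np.zeros(30), np.ones(30)]
        for _ in range(reps):
            latent = rng.normal(size=60) + shift
            a = latent + rng.normal(scale=0.7, size=60)
            b = latent + rng.normal(scale=0.7, size=60)
            _, p = compare_auc(a, b, labels)
            hits += p < 0.05
        assert 0.02 <= hits / reps <= 0.09

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValidationError):
            compare_auc([1, 2], [1, 2, 3], [0, 1])


class TestOddsRatio:
    def test_published_enhancement_or(self):
        o, lo, hi = odds_ratio(ENHANCEMENT)
        assert o == pytest.approx(3.15, abs=0.005)
        assert hi == pytest.approx(12.73, abs=0.01)

    def test_published_margin_or(self):
        o, _, _ = odds_ratio(MARGIN)
        assert o == pytest.approx(3.00, abs=0.005)

    def test_symmetric_table_is_null(self):
        o, lo, hi = odds_ratio(TwoByTwo(7, 7, 7, 7))
        assert o == 1.0 and lo < 1.0 < hi

    def test_haldane_correction_on_zero_cell(self):
        o, _, _ = odds_ratio(TwoByTwo(5, 0, 3, 7))
        assert np.isfinite(o) and o == pytest.approx(5.5 * 7.5 / (0.5 * 3.5))

    def test_cross_pattern_zeros_undefined(self):
        with pytest.raises(UndefinedOddsRatioError):
            odds_ratio(TwoByTwo(0, 5, 3, 0))


class TestLogisticFit:
    @staticmethod
    def counts_frame(t: TwoByTwo) -> pd.DataFrame:
        rows = ([(1, 1)] * t.a + [(1, 0)] * t.b + [(0, 1)] * t.c + [(0, 0)] * t.d)
        return pd.DataFrame(rows, columns=["mvi", "flag"])

    @pytest.mark.parametrize("table", [ENHANCEMENT, MARGIN, TwoByTwo(12, 7, 9, 20)])
    def test_univariate_or_equals_cross_product(self, table):
        df = self.counts_frame(table)
        fit = logistic_fit(df, "mvi", ["flag"])
        expected, _, _ = odds_ratio(table)
        assert fit.odds_ratios["flag"] == pytest.approx(expected, rel=1e-6)

    def test_published_enhancement_univariate_or(self):
        fit = logistic_fit(self.counts_frame(ENHANCEMENT), "mvi", ["flag"])
        assert fit.odds_ratios["flag"] == pytest.approx(3.15, abs=0.005)
        assert fit.ci_high["flag"] == pytest.approx(12.73, abs=0.02)

    def test_null_model_ors_near_one(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"mvi": rng.integers(0, 2, 4000),
                           "x1": rng.normal(size=4000),
                           "x2": rng.integers(0, 2, 4000)})
        fit = logistic_fit(df, "mvi", ["x1", "x2"])
        assert fit.odds_ratios["x1"] == pytest.approx(1.0, abs=0.12)
        assert fit.odds_ratios["x2"] == pytest.approx(1.0, abs=0.25)

    def test_dichotomization_applied_before_fit(self):
        df = self.counts_frame(ENHANCEMENT)
        df["score"] = df["flag"] * 2.0 + 0.5  # cutoff 1.0 recovers the flag
        fit = logistic_fit(df, "mvi", ["score"], dichotomize={"score": 1.0})
        assert fit.odds_ratios["score"] == pytest.approx(3.15, abs=0.005)

    def test_nic_collinearity_guard_keeps_highest_auc(self):
        rng = np.random.default_rng(4)
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        strong = y + rng.normal(scale=0.5, size=80)
        weak = y + rng.normal(scale=3.0, size=80)
        df = pd.DataFrame({"mvi": y, "nic_strong": strong, "nic_weak": weak})
        fit = logistic_fit(df, "mvi", ["nic_strong", "nic_weak"])
        assert fit.variables == ["nic_strong"]
        assert fit.dropped_collinear == ["nic_weak"]

    def test_separation_flagged_not_fatal(self):
        df = pd.DataFrame({"mvi": [0] * 10 + [1] * 10,
                           "x": [0.0] * 10 + [1.0] * 10})
        with pytest.warns(UserWarning, match="converge|separation"):
            fit = logistic_fit(df, "mvi", ["x"])
        assert not fit.converged


class TestReliability:
    def test_icc_identical_columns(self):
        v, cat = icc([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
        assert v == pytest.approx(1.0)
        assert cat == "excellent"

    def test_icc_independent_noise_near_zero(self):
        rng = np.random.default_rng(8)
        v, cat = icc(rng.normal(size=2000), rng.normal(size=2000))
        assert abs(v) < 0.1
        assert cat == "poor"

    def test_icc_matches_anova_decomposition(self):
        # worked 6-subject table vs the direct two-way ANOVA formula
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = np.array([1.5, 2.5, 3.5, 4.3, 5.7, 6.1])
        n, k = len(a), 2
        data = np.c_[a, b]
        grand = data.mean()
        msr = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((data.mean(axis=0) - grand) ** 2) / (k - 1)
        sse = np.sum((data - data.mean(axis=1, keepdims=True)
                      - data.mean(axis=0, keepdims=True) + grand) ** 2)
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        v, _ = icc(a, b)
        assert v == pytest.approx(expected, rel=1e-6)

    def test_icc_zero_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            icc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])

    def test_kappa_perfect_agreement(self):
        v, cat = cohen_kappa(["a", "b", "a"], ["a", "b", "a"])
        assert v == 1.0 and cat == "excellent"

    def test_kappa_independent_raters_near_zero(self):
        rng = np.random.default_rng(9)
        v, cat = cohen_kappa(rng.integers(0, 2, 5000), rng.integers(0, 2, 5000))
        assert abs(v) < 0.05 and cat == "poor"

    def test_kappa_worked_two_by_two(self):
        # rater table (20,5;10,15): po=0.7, pe=0.5 -> kappa = 0.4
        a = ["p"] * 25 + ["n"] * 25
        b = ["p"] * 20 + ["n"] * 5 + ["p"] * 10 + ["n"] * 15
        v, cat = cohen_kappa(a, b)
        assert v == pytest.approx(0.4)
        assert cat == "moderate"


class TestCohortReport:
    def test_single_feature_single_roc_row(self):
        t = generate_cohort(CohortSpec(
            features={"nic_outer1_2mm": (0.07, 0.03, 0.10, 0.03)}, seed=2))
        rep = cohort_report(t)
        assert len(rep.roc) == 1
        assert rep.roc.loc[0, "feature"] == "nic_outer1_2mm"

    def test_null_screen_admits_about_alpha(self):
        # label-permuted features: the p<0.10 screen should admit ~10%
        rng = np.random.default_rng(6)
        n_feat = 300
        df = pd.DataFrame(rng.normal(size=(36, n_feat)),
                          columns=[f"f{i}" for i in range(n_feat)])
        df["mvi"] = [0] * 22 + [1] * 14
        rep = cohort_report(df)
        rate = len(rep.screened_in) / n_feat
        assert 0.05 <= rate <= 0.16

    def test_all_missing_feature_excluded_and_logged(self):
        t = generate_cohort(CohortSpec(seed=1))
        t["nic_voi_i2_2mm"] = np.nan
        rep = cohort_report(t)
        assert "nic_voi_i2_2mm" in rep.excluded_features
        assert "nic_voi_i2_2mm" not in rep.group_comparison["feature"].values

    def test_partially_missing_feature_uses_pairwise_n(self):
        t = generate_cohort(CohortSpec(seed=4))
        t.loc[t.index[:3], "nic_voi_i1_2mm"] = np.nan  # emulates the n=33 feature
        rep = cohort_report(t)
        row = rep.group_comparison.set_index("feature").loc["nic_voi_i1_2mm"]
        assert row["n_neg"] + row["n_pos"] == 33

    def test_deterministic_given_table(self):
        t = generate_cohort(CohortSpec(seed=10))
        r1, r2 = cohort_report(t), cohort_report(t)
        pd.testing.assert_frame_equal(r1.roc, r2.roc)
        pd.testing.assert_frame_equal(r1.group_comparison, r2.group_comparison)
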