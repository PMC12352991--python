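"""Comparison statistics: signed-rank, correlation, regression, ICC, bias tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from dentage.agreement import (
    bias_table,
    icc,
    icc_panel,
    format_p,
    linreg,
    pearson_r,
    rating_matrix,
    slope_equality_test,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon_p(d):
    """Exact two-sided p by enumerating every sign assignment (2^n)."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = ss.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [np.dot(signs, ranks) for signs in itertools.product([0, 1], repeat=len(d))]
    )
    p = 2 * min((ws <= w_obs + 1e-9).mean(), (ws >= w_obs - 1e-9).mean())
    return w_obs, min(1.0, p)


class TestWilcoxon:
    def test_all_positive_small_sample(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert res.statistic == 15.0
        assert res.p_value == pytest.approx(2 / 32)

    def test_symmetric_differences_give_p_one(self):
        res = wilcoxon_signed_rank([-2, -1, 1, 2])
        assert res.p_value == 1.0
        # W+ equals half the total rank sum under perfect symmetry
        assert res.statistic == pytest.approx(0.5 * (1.5 + 1.5 + 3.5 + 3.5))

    def test_all_zero_differences_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(0.3, 1.0, rng.integers(4, 11)), 1)
        if np.all(d == 0):
            return
        w_b, p_b = brute_force_wilcoxon_p(d)
        res = wilcoxon_signed_rank(d, method="exact")
        assert res.statistic == pytest.approx(w_b)
        assert res.p_value == pytest.approx(p_b)

    def test_exact_agrees_with_scipy_when_untied(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.4, 1.0, 14)  # continuous draws: no ties
        ours = wilcoxon_signed_rank(x, method="exact")
        ref = ss.wilcoxon(x, method="exact", alternative="two-sided")
        # scipy reports min(W+, W-); p-values must agree exactly
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_exact_vs_normal_approximation_agreement(self):
        rng = np.random.default_rng(11)
        worst = 0.0
        for n in range(12, 26):
            d = np.round(rng.normal(0.2, 1.0, n), 1)
            pe = wilcoxon_signed_rank(d, method="exact").p_value
            pa = wilcoxon_signed_rank(d, method="approx").p_value
            worst = max(worst, abs(pe - pa))
        assert worst < 0.02


class TestCorrelationRegression:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_five_point_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        # hand: sums -> r = (n*Sxy - Sx*Sy) / sqrt((n*Sxx-Sx^2)(n*Syy-Sy^2))
        n, sx, sy = 5, x.sum(), y.sum()
        sxy, sxx, syy = (x * y).sum(), (x * x).sum(), (y * y).sum()
        r_hand = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
        assert pearson_r(x, y).r == pytest.approx(r_hand)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="constant"):
            linreg([2, 2, 2], [1, 2, 3])

    def test_regression_identities(self):
        x = np.arange(20.0)
        res = linreg(x, 0.5 * x)
        assert (res.slope, res.intercept, res.r_squared) == pytest.approx((0.5, 0.0, 1.0))
        res = linreg(x, x)
        assert (res.slope, res.intercept) == pytest.approx((1.0, 0.0))

    def test_null_slope_near_zero(self):
        rng = np.random.default_rng(5)
        x = np.arange(200.0)
        slopes = [linreg(x, rng.normal(3.0, 1.0, 200)).slope for _ in range(50)]
        # slope estimator SE = sigma / (sd(x) * sqrt(n)) ~ 0.00122
        assert abs(np.mean(slopes)) < 3 * 1.0 / (np.std(x) * np.sqrt(200 * 50))


class TestSlopeEquality:
    def test_identical_methods_p_one(self):
        x = np.arange(30.0)
        y = x + np.random.default_rng(0).normal(0, 0.5, 30)
        assert slope_equality_test(x, y, y) == 1.0

    def test_different_slopes_detected(self):
        rng = np.random.default_rng(1)
        x = np.linspace(8, 15, 50)
        y1 = x + rng.normal(0, 0.1, 50)
        y2 = 2 * x + rng.normal(0, 0.1, 50)
        assert slope_equality_test(x, y1, y2) < 0.001

    def test_pure_offset_not_flagged(self):
        rng = np.random.default_rng(2)
        x = np.linspace(8, 15, 60)
        y1 = x + rng.normal(0, 0.3, 60)
        y2 = y1 + 1.5
        assert slope_equality_test(x, y1, y2) > 0.9


def icc_oracle_two_way(matrix):
    """From-scratch two-way ANOVA mean squares -> ICC3/ICC2 single."""
    y = np.asarray(matrix, float)
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc3 = (msr - mse) / (msr + (k - 1) * mse)
    icc2 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return icc2, icc3


class TestICC:
    def test_identical_columns_give_one(self):
        m = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0)})
        panel = icc_panel(m)
        assert np.allclose(panel["ICC"], 1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
        assert abs(icc(m, "ICC3").value) < 0.15

    def test_matches_hand_anova_oracle(self):
        m = pd.DataFrame(
            {
                "r1": [9.0, 9.5, 10.0, 12.5, 13.5, 15.0],
                "r2": [9.25, 9.5, 10.0, 12.0, 14.0, 15.0],
            }
        )
        icc2_hand, icc3_hand = icc_oracle_two_way(m)
        assert icc(m, "ICC3").value == pytest.approx(icc3_hand, abs=1e-10)
        assert icc(m, "ICC2").value == pytest.approx(icc2_hand, abs=1e-10)

    def test_missing_cells_rejected(self):
        m = pd.DataFrame({"a": [1.0, 2, 3, 4, np.nan], "b": [1.0, 2, 3, 4, 5]})
        with pytest.raises(ValueError, match="missing"):
            icc(m)

    def test_too_few_subjects_or_raters_rejected(self):
        with pytest.raises(ValueError, match="raters"):
            icc(pd.DataFrame({"a": np.arange(8.0)}))
        with pytest.raises(ValueError, match="subjects"):
            icc(pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]}))


def tidy_estimates(rows):
    return pd.DataFrame(
        rows, columns=["subject_id", "sex", "ca_years", "method", "da_point"]
    )


class TestBiasTable:
    def test_hand_stratum_arithmetic(self):
        est = tidy_estimates(
            [
                ("a", "F", 9.0, "becker", 9.0),
                ("b", "F", 9.0, "becker", 10.0),
            ]
        )
        table = bias_table(est, methods=("becker",))
        row = table[(table["age_group"] == 9) & (table["sex"] == "F")].iloc[0]
        assert row["becker_minus_ca"] == pytest.approx(0.5)
        assert row["ca_mean"] == pytest.approx(9.0)

    def test_difference_columns_consistent_at_full_precision(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(60):
            ca = float(rng.uniform(8, 16))
            sex = "F" if i % 2 else "M"
            rows.append((f"s{i}", sex, ca, "becker", ca + rng.normal(0.2, 0.5)))
            rows.append((f"s{i}", sex, ca, "demirjian", ca + rng.normal(0.7, 0.5)))
        table = bias_table(tidy_estimates(rows))
        full = table[table["n"] > 0]
        assert np.allclose(
            full["becker_minus_ca"], full["becker_mean"] - full["ca_mean"]
        )
        assert np.allclose(
            full["demirjian_minus_becker"],
            full["demirjian_mean"] - full["becker_mean"],
        )

    def test_stratum_counts_sum_to_total(self):
        rng = np.random.default_rng(10)
        rows = []
        for i in range(40):
            ca = float(rng.uniform(8, 16))
            rows.append((f"s{i}", "F", ca, "becker", ca))
        table = bias_table(tidy_estimates(rows), methods=("becker",))
        ages = table[table["age_group"] != "total"]
        total = table[table["age_group"] == "total"]["n"].item()
        assert ages["n"].sum() == total == 40

    def test_single_subject_stratum_has_undefined_sd(self):
        est = tidy_estimates([("a", "F", 9.5, "becker", 10.0)])
        table = bias_table(est, methods=("becker",))
        row = table[(table["age_group"] == 9) & (table["sex"] == "F")].iloc[0]
        assert row["n"] == 1 and np.isnan(row["ca_sd"])

    def test_empty_stratum_emitted_with_zero_n(self):
        est = tidy_estimates(
            [("a", "F", 8.5, "becker", 9.0), ("b", "F", 10.5, "becker", 10.0)]
        )
        table = bias_table(est, methods=("becker",))
        gap = table[(table["age_group"] == 9) & (table["sex"] == "F")].iloc[0]
        assert gap["n"] == 0 and pd.isna(gap.get("ca_mean", np.nan))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bias_table(tidy_estimates([]))


class TestFormatting:
    def test_p_value_flooring(self):
        assert format_p(0.0004) == "<0.001"
        assert format_p(0.0234) == "0.023"
        assert format_p(float("nan")) == ""


class TestRatingMatrix:
    def test_pivot_by_rater(self):
        est = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b", "b"],
                "method": ["becker"] * 4,
                "rater_id": ["R1", "R2", "R1", "R2"],
                "da_point": [9.0, 9.5, 12.0, 12.0],
            }
        )
        m = rating_matrix(est, "becker")
        assert m.shape == (2, 2)
        assert m.loc["a", "R2"] == 9.5

    def test_unknown_method_rejected(self):
        est = pd.DataFrame({"subject_id": [], "method": [], "rater_id": [], "da_point": []})
        with pytest.raises(ValueError, match="no estimates"):
            rating_matrix(est, "becker")
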