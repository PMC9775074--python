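"""Statistical battery: decomposition identities, summary-table
recomputation, and independent oracles (t-test, rank-sum, enumeration,
residualization, scipy/statsmodels/pingouin cross-checks)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from alps_glymph import group_stats as gs
from alps_glymph.synthetic_data import (
    REFERENCE_AGE_SUMMARY,
    REFERENCE_EDUCATION_SUMMARY,
    REFERENCE_EPVS_COUNTS,
    REFERENCE_GENDER_COUNTS,
)


class TestAnova:
    def test_identical_group_means_give_zero_f(self):
        res = gs.anova_oneway([[1.0, 2.0, 3.0], [2.0, 2.0, 2.0], [3.0, 2.0, 1.0]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 12)
        f_res = gs.anova_oneway([a, b])
        t, p = stats.ttest_ind(a, b)  # pooled-variance t-test oracle
        assert f_res.statistic == pytest.approx(t**2, rel=1e-10)
        assert f_res.p_value == pytest.approx(p, rel=1e-10)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(m, 1, n) for m, n in ((0, 10), (0.3, 14), (0.8, 8))]
        mine = gs.anova_oneway(groups)
        f, p = stats.f_oneway(*groups)
        assert mine.statistic == pytest.approx(f, rel=1e-10)
        assert mine.p_value == pytest.approx(p, rel=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_summary_anova_equals_raw_anova(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        groups = [rng.normal(rng.normal(), 1 + rng.random(), int(rng.integers(2, 20)))
                  for _ in range(k)]
        raw = gs.anova_oneway(groups)
        summ = gs.anova_from_summary(
            [len(g) for g in groups],
            [g.mean() for g in groups],
            [g.std(ddof=1) for g in groups],
        )
        assert summ.statistic == pytest.approx(raw.statistic, abs=1e-10, rel=1e-10)
        assert summ.df == raw.df

    def test_age_summary_reproduces_published_f(self):
        """Group age moments reproduce the published F statistic (12.87)."""
        res = gs.anova_from_summary(**REFERENCE_AGE_SUMMARY)
        assert res.statistic == pytest.approx(12.87, abs=0.02)
        assert res.df == (3, 185)
        assert res.p_value < 0.001

    def test_education_summary_reproduces_published_f(self):
        res = gs.anova_from_summary(**REFERENCE_EDUCATION_SUMMARY)
        assert res.statistic == pytest.approx(21.75, rel=0.005)
        assert res.p_value < 0.001

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            gs.anova_oneway([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            gs.anova_from_summary([2], [1.0], [1.0])


class TestGlmAdjusted:
    def test_no_covariates_reduces_to_anova(self, rng):
        y = rng.normal(0, 1, 40)
        g = np.repeat(["a", "b", "c", "d"], 10)
        glm = gs.glm_adjusted(y, g)
        anova = gs.anova_oneway([y[g == lv] for lv in "abcd"])
        assert glm.statistic == pytest.approx(anova.statistic, rel=1e-10)
        assert glm.p_value == pytest.approx(anova.p_value, rel=1e-10)

    def test_pure_covariate_outcome_has_no_group_effect(self, rng):
        cov = rng.normal(0, 1, (60, 2))
        y = 2.0 + 1.5 * cov[:, 0] - 0.7 * cov[:, 1]
        g = np.tile(["a", "b", "c"], 20)
        res = gs.glm_adjusted(y, g, cov)
        # y lies exactly in the covariate span, so every adjusted group
        # contrast is zero up to round-off (the F ratio itself is 0/0 there)
        assert np.allclose(res.posthoc["estimate"], 0.0, atol=1e-8)

    def test_recovers_built_in_adjusted_group_gap(self, rng):
        n = 200
        g = np.repeat(["ctrl", "case"], n // 2)
        age = rng.normal(65, 8, n)
        gap = 0.8
        y = 0.05 * age + gap * (g == "case") + rng.normal(0, 0.5, n)
        res = gs.glm_adjusted(y, g, age[:, None], covariate_names=["age"])
        row = res.posthoc.iloc[0]
        assert row["contrast"] == "case - ctrl"
        assert abs(row["estimate"] - gap) < 3 * row["se"]

    def test_bonferroni_never_below_raw(self, rng):
        y = rng.normal(0, 1, 48)
        g = np.tile(["a", "b", "c", "d"], 12)
        res = gs.glm_adjusted(y, g, rng.normal(size=(48, 1)))
        assert (res.posthoc["p_bonferroni"] >= res.posthoc["p_raw"] - 1e-15).all()
        assert res.extra["bonferroni_m"] == 6

    def test_collinear_design_names_columns(self, rng):
        y = rng.normal(0, 1, 30)
        g = np.tile(["a", "b"], 15)
        cov = np.column_stack([np.ones(30), np.ones(30)])  # duplicated constant
        with pytest.raises(ValueError, match="collinear"):
            gs.glm_adjusted(y, g, cov)


class TestKruskalWallis:
    def test_matches_brute_force_definition_no_ties(self):
        """Small-sample H recomputed from the rank-sum definition."""
        groups = [[1.2, 3.4, 5.1], [2.2, 4.7], [0.3, 6.8, 7.7, 2.9]]
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        start, h = 0, 0.0
        for g in groups:
            r = ranks[start : start + len(g)]
            h += r.sum() ** 2 / len(g)
            start += len(g)
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        res = gs.kruskal_wallis(groups)
        assert res.statistic == pytest.approx(h, rel=1e-12)

    def test_two_groups_consistent_with_rank_sum(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        res = gs.kruskal_wallis([a, b])
        # with two groups H equals the squared standardized rank-sum statistic
        u_p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                 use_continuity=False).pvalue
        assert res.p_value == pytest.approx(u_p, rel=1e-6)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            gs.kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])


class TestCategorical:
    def test_gender_table_reproduces_published_chi_square(self):
        table = np.array([REFERENCE_GENDER_COUNTS["female"], REFERENCE_GENDER_COUNTS["male"]])
        res = gs.chi_square_test(table)
        assert res.statistic == pytest.approx(0.106, abs=5e-4)
        assert res.p_value == pytest.approx(0.991, abs=5e-4)
        assert res.df == (3,)

    def test_epvs_table_reproduces_published_chi_square(self):
        table = np.array([REFERENCE_EPVS_COUNTS["present"], REFERENCE_EPVS_COUNTS["absent"]])
        res = gs.chi_square_test(table)
        assert res.statistic == pytest.approx(25.293, abs=5e-4)

    def test_table_equal_to_expected_gives_zero(self):
        table = np.array([[10, 20, 30], [20, 40, 60]])
        assert gs.chi_square_test(table).statistic == pytest.approx(0.0, abs=1e-12)

    def test_chi_square_invariant_to_permutation(self):
        table = np.array([[5, 9, 2], [7, 3, 8]])
        base = gs.chi_square_test(table).statistic
        assert gs.chi_square_test(table[::-1]).statistic == pytest.approx(base)
        assert gs.chi_square_test(table[:, [2, 0, 1]]).statistic == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            gs.chi_square_test(np.array([[0, 5], [0, 7]]))

    def test_fisher_matches_hypergeometric_enumeration(self):
        """Two-sided p as the sum of all table probabilities <= observed."""
        table = np.array([[1, 9], [11, 3]])
        r1, r2 = table.sum(axis=1)
        c1 = table[:, 0].sum()
        n = table.sum()
        obs_p = stats.hypergeom.pmf(table[0, 0], n, r1, c1)
        total = sum(
            p for k in range(max(0, c1 - r2), min(r1, c1) + 1)
            if (p := stats.hypergeom.pmf(k, n, r1, c1)) <= obs_p * (1 + 1e-9)
        )
        res = gs.fisher_exact(table)
        assert res.p_value == pytest.approx(total, rel=1e-9)

    def test_fisher_identical_rows_give_p_one(self):
        assert gs.fisher_exact([[4, 6], [4, 6]]).p_value == pytest.approx(1.0)

    def test_fisher_row_swap_symmetric(self):
        a = gs.fisher_exact([[2, 8], [9, 1]]).p_value
        b = gs.fisher_exact([[9, 1], [2, 8]]).p_value
        assert a == pytest.approx(b)

    def test_fisher_requires_2x2(self):
        with pytest.raises(ValueError, match="2x2"):
            gs.fisher_exact(np.ones((2, 3)))


class TestCorrelations:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = gs.pearson_corr(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)

    def test_hand_worked_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert gs.pearson_corr(x, y).statistic == pytest.approx(r_hand, rel=1e-12)

    def test_independent_large_n_near_zero(self, rng):
        x, y = rng.normal(0, 1, 5000), rng.normal(0, 1, 5000)
        assert abs(gs.pearson_corr(x, y).statistic) < 0.05

    def test_partial_with_no_covariates_equals_pearson(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        assert gs.partial_corr(x, y, np.empty((30, 0))).statistic == pytest.approx(
            gs.pearson_corr(x, y).statistic
        )

    def test_outcome_dominated_by_covariate_partials_to_zero(self, rng):
        x = rng.normal(0, 1, 500)
        z = rng.normal(0, 1, 500)
        y = z + 1e-6 * rng.normal(0, 1, 500)  # essentially the covariate itself
        res = gs.partial_corr(x, y, z[:, None])
        assert abs(res.statistic) < 0.1

    def test_outcome_exactly_equal_to_covariate_is_degenerate(self, rng):
        x = rng.normal(0, 1, 50)
        z = rng.normal(0, 1, 50)
        with pytest.raises(ValueError, match="zero residual variance"):
            gs.partial_corr(x, z.copy(), z[:, None])

    def test_matches_residualize_then_correlate_oracle(self, rng):
        """Independent brute-force residualization agrees to 1e-12."""
        n, q = 50, 3
        z = rng.normal(0, 1, (n, q))
        x = z @ np.array([0.5, -0.2, 0.1]) + rng.normal(0, 1, n)
        y = z @ np.array([-0.3, 0.4, 0.2]) + 0.4 * x + rng.normal(0, 1, n)
        res = gs.partial_corr(x, y, z)
        d = np.column_stack([np.ones(n), z])
        hat = d @ np.linalg.inv(d.T @ d) @ d.T
        rx, ry = x - hat @ x, y - hat @ y
        r_oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.statistic == pytest.approx(r_oracle, abs=1e-12)

    def test_matches_pingouin_partial_correlation(self, rng):
        pg = pytest.importorskip("pingouin")
        n = 60
        z1, z2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        x = 0.5 * z1 + rng.normal(0, 1, n)
        y = -0.3 * z2 + 0.4 * x + rng.normal(0, 1, n)
        mine = gs.partial_corr(x, y, np.column_stack([z1, z2]))
        theirs = pg.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "z1": z1, "z2": z2}),
            x="x", y="y", covar=["z1", "z2"],
        )
        assert mine.statistic == pytest.approx(float(theirs["r"].iloc[0]), abs=1e-9)
        assert mine.p_value == pytest.approx(float(theirs["p_val"].iloc[0]), abs=1e-9)

    def test_collinear_covariates_rejected(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        z = np.column_stack([np.arange(20.0), 2 * np.arange(20.0)])
        with pytest.raises(ValueError, match="collinear"):
            gs.partial_corr(x, y, z)


class TestGroupSummary:
    def test_normal_variable_reported_as_mean_sd(self, rng):
        df = pd.DataFrame({
            "group": np.repeat(["a", "b"], 40),
            "v": np.concatenate([rng.normal(0, 1, 40), rng.normal(1, 1, 40)]),
        })
        summ = gs.summarize_groups(df, "v")
        assert summ.normal
        assert set(summ.table.columns) == {"n", "mean", "sd"}

    def test_skewed_variable_reported_as_median_iqr(self, rng):
        df = pd.DataFrame({
            "group": np.repeat(["a", "b"], 60),
            "v": np.exp(rng.normal(0, 1.5, 120)),
        })
        summ = gs.summarize_groups(df, "v")
        assert not summ.normal
        assert set(summ.table.columns) == {"n", "median", "iqr"}
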