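import math

import numpy as np
import pytest
from scipy import stats

from craterdemog.ecomorph import (
    LipidCorrectionParams,
    anova_oneway,
    anova_twoway,
    compute_bhi,
    kde_density,
    lipid_correct_d13c,
    manova_pillai,
    welch_t,
)


class TestBhi:
    def test_direct_division(self):
        assert compute_bhi(100.0, 43.0) == pytest.approx(0.430)

    def test_equal_measures_give_one(self):
        assert compute_bhi(57.3, 57.3) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            compute_bhi(0.0, 10.0)


class TestWelch:
    def test_hand_computed_toy(self):
        # a=[1,2,3,4], b=[2,4,6,8]: va=5/3, vb=20/3
        a, b = [1, 2, 3, 4], [2, 4, 6, 8]
        va, vb = 5 / 3, 20 / 3
        se = math.sqrt(va / 4 + vb / 4)
        t_exp = (2.5 - 5.0) / se
        df_exp = (va / 4 + vb / 4) ** 2 / ((va / 4) ** 2 / 3 + (vb / 4) ** 2 / 3)
        r = welch_t(a, b)
        assert r.statistic == pytest.approx(t_exp, rel=1e-12)
        assert r.df == pytest.approx(df_exp, rel=1e-12)

    def test_identical_samples(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=10), rng.normal(1.0, 2.0, size=15)
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])

    def test_type_one_error_calibrated_under_null(self):
        """At alpha = 0.05 on identically distributed groups the rejection
        rate over 5000 replicates is 0.05 +- 0.01."""
        rng = np.random.default_rng(2024)
        n_rep = 5000
        x = rng.normal(size=(n_rep, 12))
        y = rng.normal(size=(n_rep, 12))
        # vectorized Welch for speed; equivalent formulas
        va, vb = x.var(axis=1, ddof=1) / 12, y.var(axis=1, ddof=1) / 12
        t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 11 + vb**2 / 11)
        p = 2 * stats.t.sf(np.abs(t), df)
        # spot-check the vectorization against the scalar implementation
        r0 = welch_t(x[0], y[0])
        assert r0.statistic == pytest.approx(t[0]) and r0.p_value == pytest.approx(p[0])
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.01)


class TestLipidCorrection:
    def test_formula_oracle_at_cn6(self):
        # direct evaluation of the mass-balance equations
        p = LipidCorrectionParams()
        L = 93.0 / (1.0 + 1.0 / (0.246 * 6.0 - 0.775))
        expected = -30.0 + 7.018 * (0.048 + 3.90 / (1.0 + 287.0 / L))
        assert lipid_correct_d13c(-30.0, 6.0, p) == pytest.approx(expected, rel=1e-12)

    def test_zero_lipid_reduces_to_protein_baseline(self):
        p = LipidCorrectionParams()
        cn0 = p.b / p.a  # C:N at which estimated lipid content hits zero
        assert lipid_correct_d13c(-30.0, cn0, p) == pytest.approx(-30.0 + p.D * p.I)

    def test_correction_strictly_increasing_in_cn(self):
        vals = [lipid_correct_d13c(-30.0, cn) for cn in np.linspace(3.2, 12.0, 40)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_invalid_cn_rejected(self):
        with pytest.raises(ValueError):
            lipid_correct_d13c(-30.0, 0.0)


class TestManova:
    def test_two_group_toy_against_hand_eigen(self):
        # 3 obs per group, 2 variables; H and E assembled by hand
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0],
                      [3.0, 2.0], [4.0, 1.0], [5.0, 3.0]])
        g = ["a"] * 3 + ["b"] * 3
        grand = X.mean(axis=0)
        H = np.zeros((2, 2))
        E = np.zeros((2, 2))
        for lab in ("a", "b"):
            sub = X[np.array(g) == lab]
            d = (sub.mean(axis=0) - grand)[:, None]
            H += 3 * d @ d.T
            c = sub - sub.mean(axis=0)
            E += c.T @ c
        pillai_exp = np.trace(np.linalg.solve(H + E, H))
        r = manova_pillai(X, g)
        assert r.statistic == pytest.approx(pillai_exp, rel=1e-10)

    def test_matches_statsmodels(self):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 2))
        X[20:] += [0.8, -0.3]
        g = ["a"] * 20 + ["b"] * 20
        r = manova_pillai(X, g)
        df = pd.DataFrame({"y1": X[:, 0], "y2": X[:, 1], "g": g})
        mv = MANOVA.from_formula("y1 + y2 ~ g", data=df).mv_test()
        tab = mv.results["g"]["stat"]
        assert r.statistic == pytest.approx(tab.loc["Pillai's trace", "Value"], rel=1e-8)
        assert r.p_value == pytest.approx(tab.loc["Pillai's trace", "Pr > F"], rel=1e-6)

    def test_identical_groups_give_zero_trace(self):
        X = np.vstack([np.eye(3, 2) + 0.1, np.eye(3, 2) + 0.1])
        r = manova_pillai(X, ["a"] * 3 + ["b"] * 3)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_one_column_reduces_to_oneway_anova_f(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=30)
        y[15:] += 1.0
        g = ["a"] * 15 + ["b"] * 15
        r_m = manova_pillai(y[:, None], g)
        r_a = anova_oneway(y, g)
        V = r_m.statistic
        # for p = 1: F = (V/(1-V)) * df_e/df_h equals the ANOVA F
        s, dfh, dfe = 1, 1, 28
        f_from_pillai = (V / (1 - V)) * dfe / dfh
        assert f_from_pillai == pytest.approx(r_a.statistic, rel=1e-9)
        assert r_m.p_value == pytest.approx(r_a.p_value, rel=1e-9)

    def test_collinear_columns_rejected(self):
        X = np.arange(6, dtype=float).reshape(6, 1)
        X = np.hstack([X, 2 * X])
        with pytest.raises(ValueError):
            manova_pillai(X, ["a"] * 3 + ["b"] * 3)


class TestAnova:
    def test_oneway_sums_of_squares_oracle(self):
        # 2 groups x 3 obs; SSB/SSW by hand
        y = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 8.0])
        g = ["a"] * 3 + ["b"] * 3
        ssb = 3 * (2.0 - 4.0) ** 2 + 3 * (6.0 - 4.0) ** 2
        ssw = sum((v - 2.0) ** 2 for v in [1, 2, 3]) + sum(
            (v - 6.0) ** 2 for v in [4, 6, 8]
        )
        f_exp = (ssb / 1) / (ssw / 4)
        r = anova_oneway(y, g)
        assert r.statistic == pytest.approx(f_exp, rel=1e-12)
        assert r.df == (1.0, 4.0)

    def test_all_equal_values_is_degenerate_error(self):
        with pytest.raises(ValueError):
            anova_oneway([2.0] * 6, ["a"] * 3 + ["b"] * 3)

    def test_twoway_against_sequential_projection_oracle(self):
        """Small unbalanced design: Type-I F values recomputed from nested
        OLS residual sums of squares built with raw design matrices."""
        y = np.array([3.1, 2.9, 3.5, 4.2, 4.0, 5.1, 5.3, 4.8, 6.2, 6.0, 5.5])
        A = np.array(["s1"] * 5 + ["s2"] * 6)
        B = np.array(["c", "c", "t", "t", "t", "c", "c", "c", "t", "t", "t"])

        def rss(*terms):
            cols = [np.ones_like(y)]
            for t in terms:
                levels = sorted(set(t))[1:]
                for lv in levels:
                    cols.append((t == lv).astype(float))
            X = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(((y - X @ beta) ** 2).sum())

        AB = np.array([a + ":" + b for a, b in zip(A, B)])
        rss0, rssA = rss(), rss(A)
        rssAB_ = rss(A, B)
        rssFull = rss(A, B, AB)
        df_resid = len(y) - len(set(A)) * len(set(B))
        ms_resid = rssFull / df_resid
        f_a = (rss0 - rssA) / 1 / ms_resid
        f_b = (rssA - rssAB_) / 1 / ms_resid
        f_ab = (rssAB_ - rssFull) / 1 / ms_resid
        ra, rb, rab = anova_twoway(y, A, B)
        assert ra.statistic == pytest.approx(f_a, rel=1e-8)
        assert rb.statistic == pytest.approx(f_b, rel=1e-8)
        assert rab.statistic == pytest.approx(f_ab, rel=1e-8)

    def test_twoway_empty_cell_rejected(self):
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        A = ["s1", "s1", "s2", "s2", "s2"]
        B = ["c", "c", "c", "t", "t"]  # cell (s1, t) unoccupied
        with pytest.raises(ValueError, match="empty"):
            anova_twoway(y, A, B)


class TestKde:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(11)
        grid, dens = kde_density(rng.normal(size=60))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_matches_brute_force_kernel_sum(self):
        vals = np.array([0.0, 1.0, 3.0])
        grid, dens = kde_density(vals, bandwidth=0.5)
        brute = np.mean(
            [stats.norm.pdf(grid, loc=v, scale=0.5) for v in vals], axis=0
        )
        assert np.allclose(dens, brute, atol=1e-10)

    def test_repeated_value_fixed_bandwidth_is_gaussian(self):
        grid, dens = kde_density([2.0, 2.0, 2.0], bandwidth=0.3)
        assert np.allclose(dens, stats.norm.pdf(grid, loc=2.0, scale=0.3))

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            kde_density([1.0])
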