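"""Core statistical engine: blockwise OLS, residuals, effect sizes, MANCOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from resiliometry.stats import (chi_square_independence, cohens_d,
                                hierarchical_regression, mancova,
                                partial_correlation, reverse_coded_residuals,
                                tertile_split, two_proportion_z)


def make_df(n=300, seed=0, k=4):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])
    df["y"] = 0.4 * df["x0"] - 0.3 * df["x1"] + rng.normal(size=n)
    return df


class TestHierarchicalRegression:
    def test_single_predictor_beta_equals_r_and_r2(self):
        df = make_df()
        res = hierarchical_regression(df, "y", [["x0"]])
        r = df["y"].corr(df["x0"])
        assert res.final.betas["x0"] == pytest.approx(r, abs=1e-10)
        assert res.final.r_squared == pytest.approx(r**2, abs=1e-10)

    def test_delta_r2_matches_two_model_oracle(self):
        df = make_df(seed=3)
        res = hierarchical_regression(df, "y", [["x0", "x1"], ["x2", "x3"]])

        def oracle_r2(cols):
            X = np.column_stack([np.ones(len(df))] + [df[c] for c in cols])
            y = df["y"].to_numpy()
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            return 1 - resid.var() / y.var()

        r2_a = oracle_r2(["x0", "x1"])
        r2_b = oracle_r2(["x0", "x1", "x2", "x3"])
        assert res.steps[0].r_squared == pytest.approx(r2_a, abs=1e-10)
        assert res.steps[1].delta_r_squared == pytest.approx(r2_b - r2_a, abs=1e-10)

    def test_r2_monotone_and_sums(self):
        df = make_df(seed=7)
        res = hierarchical_regression(df, "y", [["x0"], ["x1"], ["x2"], ["x3"]])
        r2s = [s.r_squared for s in res.steps]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))
        assert sum(s.delta_r_squared for s in res.steps) == pytest.approx(res.final.r_squared)

    def test_delta_f_formula(self):
        df = make_df(seed=9)
        res = hierarchical_regression(df, "y", [["x0"], ["x1", "x2"]])
        s = res.steps[1]
        n = len(df)
        expected = (s.delta_r_squared / 2) / ((1 - s.r_squared) / (n - 3 - 1))
        assert s.delta_f == pytest.approx(expected)

    def test_rank_deficiency_names_column(self):
        df = make_df()
        df["x_dup"] = df["x0"]
        with pytest.raises(ValueError, match="x_dup"):
            hierarchical_regression(df, "y", [["x0", "x_dup"]])

    def test_empty_block_error(self):
        with pytest.raises(ValueError, match="block"):
            hierarchical_regression(make_df(), "y", [["x0"], []])


class TestReverseCodedResiduals:
    def test_exact_linear_function_gives_zero_residuals(self):
        x = np.arange(20.0)
        assert np.allclose(reverse_coded_residuals(3 * x + 1, x), 0)

    def test_standardization_and_orthogonality(self, rng):
        x = rng.normal(size=400)
        y = 0.5 * x + rng.normal(size=400)
        r = reverse_coded_residuals(y, x)
        assert r.mean() == pytest.approx(0, abs=1e-10)
        assert r.std(ddof=1) == pytest.approx(1, abs=1e-10)
        assert np.corrcoef(r, x)[0, 1] == pytest.approx(0, abs=1e-10)

    def test_reverse_coding_orientation(self, rng):
        # children with fewer difficulties than predicted get positive scores
        x = rng.normal(size=100)
        y = x.copy()
        y[0] -= 10.0                       # one child far better than expected
        r = reverse_coded_residuals(y, x)
        assert r[0] > 0

    def test_outcome_sign_flip_flips_residuals(self, rng):
        x = rng.normal(size=200)
        y = 0.3 * x + rng.normal(size=200)
        np.testing.assert_allclose(reverse_coded_residuals(-y, x),
                                   -reverse_coded_residuals(y, x), atol=1e-10)

    def test_zero_variance_predictor_error(self):
        with pytest.raises(ValueError, match="variance"):
            reverse_coded_residuals(np.arange(12.0), np.ones(12))


class TestCohensD:
    # Printed adaptation-group contrasts (mean, sd per group) and their
    # published effect sizes; the RMS-pooled form reproduces all of them.
    PRINTED = [
        ((68.23, 5.80, 39), (62.70, 6.61, 79), 0.89),   # child-parent rel, R vs M
        ((0.39, 0.76, 39), (-0.46, 0.94, 79), 0.99),    # self-concept, R vs M
        ((68.84, 4.67, 72), (63.40, 6.37, 47), 0.97),   # child-parent rel, C vs HV
        ((22.23, 4.08, 39), (19.09, 4.15, 79), 0.76),   # self-control, R vs M
        ((0.44, 0.71, 72), (-0.39, 0.83, 47), 1.07),    # self-concept, C vs HV
        ((-0.01, 0.87, 50), (-0.60, 1.09, 71), 0.60),   # teacher self-concept, R vs M
    ]

    @pytest.mark.parametrize("a,b,expected", PRINTED)
    def test_reproduces_printed_contrasts(self, a, b, expected):
        assert round(cohens_d(*a, *b), 2) == pytest.approx(expected)

    def test_equal_means_zero_and_antisymmetry(self):
        assert cohens_d(5, 1, 10, 5, 2, 10) == 0
        assert cohens_d(3, 1, 8, 1, 2, 9) == -cohens_d(1, 2, 9, 3, 1, 8)

    def test_scale_invariance(self):
        assert cohens_d(10, 2, 5, 8, 3, 5) == pytest.approx(cohens_d(50, 10, 5, 40, 15, 5))

    def test_df_pooling_differs(self):
        a, b, _ = self.PRINTED[0]
        assert cohens_d(*a, *b, pooling="df") != cohens_d(*a, *b, pooling="rms")

    def test_nonpositive_sd_error(self):
        with pytest.raises(ValueError):
            cohens_d(1, 0, 5, 2, 1, 5)


class TestPartialCorrelation:
    def test_zero_conditioning_returns_input(self):
        assert partial_correlation(0.37, 0, 0) == pytest.approx(0.37)

    def test_printed_residual_correlation(self):
        assert round(partial_correlation(0.42, 0.26, 0.13), 2) == pytest.approx(0.40)

    def test_matches_residual_simulation_oracle(self):
        # correlation of the two partialled residual vectors on a large
        # trivariate normal with exactly the input correlation structure
        r_xy, r_xz, r_yz = 0.5, 0.3, -0.2
        C = np.array([[1, r_xy, r_xz], [r_xy, 1, r_yz], [r_xz, r_yz, 1]])
        rng = np.random.default_rng(11)
        X = rng.standard_normal((200_000, 3)) @ np.linalg.cholesky(C).T
        rx = reverse_coded_residuals(X[:, 0], X[:, 2])
        ry = reverse_coded_residuals(X[:, 1], X[:, 2])
        sim = np.corrcoef(rx, ry)[0, 1]
        assert partial_correlation(r_xy, r_xz, r_yz) == pytest.approx(sim, abs=0.01)

    def test_degenerate_error(self):
        with pytest.raises(ValueError):
            partial_correlation(0.5, 1.0, 0.2)


class TestTwoProportionZ:
    def test_equal_proportions(self):
        z, _ = two_proportion_z(10, 50, 20, 100)
        assert z == pytest.approx(0)

    def test_printed_group_share_comparison(self):
        z, p = two_proportion_z(72, 158, 39, 159)
        assert round(z, 2) == pytest.approx(4.02)
        assert p < 0.001

    def test_pooled_variant_differs(self):
        z_u, _ = two_proportion_z(72, 158, 39, 159)
        z_p, _ = two_proportion_z(72, 158, 39, 159, pooled=True)
        assert round(z_p, 2) == pytest.approx(3.93)
        assert z_u != z_p

    def test_matches_permutation_oracle_on_small_counts(self):
        k1, n1, k2, n2 = 11, 24, 4, 22
        z, _ = two_proportion_z(k1, n1, k2, n2)
        rng = np.random.default_rng(5)
        pool = np.array([1] * (k1 + k2) + [0] * (n1 + n2 - k1 - k2))
        diffs = np.empty(20_000)
        for b in range(len(diffs)):
            rng.shuffle(pool)
            diffs[b] = pool[:n1].mean() - pool[n1:].mean()
        z_perm = (k1 / n1 - k2 / n2) / diffs.std()
        assert abs(z) == pytest.approx(abs(z_perm), abs=0.3)

    def test_degenerate_error(self):
        with pytest.raises(ValueError):
            two_proportion_z(0, 10, 10, 10)


class TestTertileSplit:
    def test_balanced_split(self):
        labels = tertile_split(np.arange(1, 10))
        assert (labels == np.array(["low"] * 3 + ["mid"] * 3 + ["high"] * 3)).all()

    def test_boundary_ties_go_to_lower_stratum(self):
        v = np.array([1, 1, 1, 1, 2, 2, 3, 3, 3], dtype=float)
        labels = tertile_split(v)
        assert set(labels[v == 1]) == {"low"}
        assert (labels == tertile_split(v)).all()    # deterministic

    def test_group_sizes_near_thirds_on_continuous_data(self, rng):
        labels = tertile_split(rng.normal(size=475))
        counts = pd.Series(labels).value_counts()
        assert counts.max() - counts.min() <= 2

    def test_too_few_distinct_values_error(self):
        with pytest.raises(ValueError, match="distinct"):
            tertile_split(np.array([1.0, 2.0] * 10))


class TestMancova:
    def test_one_dv_no_covariate_equals_anova_f(self, rng):
        groups = np.repeat(["a", "b", "c"], 30)
        y = rng.normal(size=90) + (groups == "b") * 0.5
        res = mancova(y, groups)
        f_ref = sps.f_oneway(y[groups == "a"], y[groups == "b"], y[groups == "c"])
        assert res.f_value == pytest.approx(f_ref.statistic, rel=1e-9)
        assert res.pvalue == pytest.approx(f_ref.pvalue, rel=1e-6)
        assert res.univariate.loc[0, "F"] == pytest.approx(f_ref.statistic, rel=1e-9)

    def test_wilks_matches_sscp_oracle(self, rng):
        groups = np.repeat(["g1", "g2", "g3"], 8)
        Y = rng.normal(size=(24, 2))
        Y[groups == "g2"] += [0.8, -0.3]
        res = mancova(Y, groups)
        # direct SSCP computation from group means
        grand = Y.mean(axis=0)
        E = np.zeros((2, 2))
        H = np.zeros((2, 2))
        for g in ("g1", "g2", "g3"):
            sub = Y[groups == g]
            d = sub - sub.mean(axis=0)
            E += d.T @ d
            m = (sub.mean(axis=0) - grand)[:, None]
            H += len(sub) * (m @ m.T)
        lam = np.linalg.det(E) / np.linalg.det(E + H)
        assert res.wilks_lambda == pytest.approx(lam, rel=1e-9)
        assert 0 < res.wilks_lambda <= 1
        assert 0 <= res.partial_eta_squared < 1

    def test_matches_statsmodels_manova_with_covariate(self, rng):
        from statsmodels.multivariate.manova import MANOVA
        n = 120
        groups = np.repeat(["a", "b", "c", "d"], n // 4)
        cov = rng.normal(size=n)
        Y = rng.normal(size=(n, 3)) + cov[:, None] * 0.4
        Y[groups == "a"] += [0.5, 0, -0.2]
        res = mancova(Y, groups, covariate=cov)
        df = pd.DataFrame(Y, columns=["y1", "y2", "y3"])
        df["g"] = groups
        df["cov"] = cov
        mv = MANOVA.from_formula("y1 + y2 + y3 ~ C(g) + cov", data=df).mv_test()
        tbl = mv.results["C(g)"]["stat"]
        assert res.wilks_lambda == pytest.approx(tbl.loc["Wilks' lambda", "Value"], rel=1e-6)
        assert res.f_value == pytest.approx(tbl.loc["Wilks' lambda", "F Value"], rel=1e-6)

    def test_identical_group_means_lambda_near_one(self, rng):
        groups = np.repeat(["a", "b"], 50)
        Y = rng.normal(size=(100, 2))
        res = mancova(Y, groups)
        assert res.wilks_lambda > 0.9
        assert res.partial_eta_squared < 0.1

    def test_small_group_error(self, rng):
        groups = np.array(["a"] * 2 + ["b"] * 30)
        with pytest.raises(ValueError, match="n <="):
            mancova(rng.normal(size=(32, 3)), groups)


class TestChiSquare:
    def test_independence_product_table_is_zero(self):
        row = np.array([0.2, 0.5, 0.3])
        col = np.array([0.4, 0.6])
        table = 600 * np.outer(row, col)
        chi2, df, p = chi_square_independence(table)
        assert chi2 == pytest.approx(0, abs=1e-10)

    def test_three_by_three_df(self):
        chi2, df, _ = chi_square_independence(np.array([[20, 15, 10], [12, 18, 22], [9, 14, 30]]))
        assert df == 4

    def test_two_by_two_matches_expected_count_formula(self):
        t = np.array([[12, 8], [5, 15]], dtype=float)
        n = t.sum()
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
        oracle = ((t - expected) ** 2 / expected).sum()
        chi2, df, _ = chi_square_independence(t)
        assert chi2 == pytest.approx(oracle) and df == 1

    def test_zero_margin_error(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_independence(np.array([[0, 0], [5, 3]]))


class TestIndependentLibraryCrossChecks:
    """Route-independent verification against pingouin's implementations."""

    def test_partial_correlation_matches_pingouin(self, rng):
        import pingouin as pg
        df = pd.DataFrame(rng.normal(size=(300, 3)), columns=["x", "y", "z"])
        df["y"] += 0.5 * df["x"] + 0.3 * df["z"]
        ours = partial_correlation(df["x"].corr(df["y"]),
                                   df["x"].corr(df["z"]),
                                   df["y"].corr(df["z"]))
        theirs = pg.partial_corr(df, x="x", y="y", covar="z").loc["pearson", "r"]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_cronbach_alpha_matches_pingouin(self, rng):
        import pingouin as pg
        from resiliometry.scoring import cronbach_alpha
        X = rng.normal(size=(120, 6)) + rng.normal(size=(120, 1))
        theirs = pg.cronbach_alpha(data=pd.DataFrame(X))[0]
        assert cronbach_alpha(X) == pytest.approx(theirs, abs=1e-10)
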