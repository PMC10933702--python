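"""RAM engine: implied moments, FIML likelihood, fitting, SEs,
standardisation."""

import numpy as np
import pytest
from scipy import stats

import twinclpm as t
from twinclpm.sem import ModelSpec, ObservedMatrix, _saturated_spec


def _regression_spec():
    """x -> y with free means, variances and slope."""
    spec = ModelSpec(["x", "y"], ["x", "y"])
    spec.add_mean("x", label="mx")
    spec.add_mean("y", label="my")
    spec.add_cov("x", "x", label="vx")
    spec.add_cov("y", "y", label="vy")
    spec.add_path("x", "y", label="b")
    return spec


class TestImpliedMoments:
    def test_no_structure_returns_s_and_m(self):
        spec = ModelSpec(["a", "b"], ["a", "b"])
        spec.add_cov("a", "a", label="v1")
        spec.add_cov("b", "b", label="v2")
        mu, Sigma = t.implied_moments(spec, {"v1": 1.0, "v2": 2.0})
        np.testing.assert_allclose(Sigma, np.diag([1.0, 2.0]))
        np.testing.assert_allclose(mu, 0.0)

    def test_path_tracing_single_regression(self):
        spec = _regression_spec()
        mu, Sigma = t.implied_moments(
            spec, {"mx": 0, "my": 0, "vx": 1.0, "vy": 0.75, "b": 0.5})
        np.testing.assert_allclose(Sigma[0, 1], 0.5)
        np.testing.assert_allclose(Sigma[1, 1], 1.0)  # 0.5^2 * 1 + 0.75

    def test_monte_carlo_oracle(self):
        # chain x -> y -> z with nonzero means, vs 1e6 structural draws
        spec = ModelSpec(["x", "y", "z"], ["x", "y", "z"])
        for v, m in zip("xyz", (1.0, -0.5, 0.2)):
            spec.add_mean(v, value=m)
            spec.add_cov(v, v, value={"x": 1.0, "y": 0.5, "z": 0.8}[v])
        spec.add_path("x", "y", value=0.6)
        spec.add_path("y", "z", value=-0.4)
        spec.add_path("x", "z", value=0.3)
        mu, Sigma = t.implied_moments(spec, np.zeros(0))
        rng = np.random.default_rng(123)
        n = 1_000_000
        x = 1.0 + rng.standard_normal(n)
        y = -0.5 + 0.6 * x + np.sqrt(0.5) * rng.standard_normal(n)
        z = 0.2 + 0.3 * x - 0.4 * y + np.sqrt(0.8) * rng.standard_normal(n)
        draws = np.column_stack([x, y, z])
        mc_mu = draws.mean(axis=0)
        mc_S = np.cov(draws.T, ddof=0)
        # 3 MC standard errors; var of a covariance estimate ~ (s_ii s_jj + s_ij^2)/n
        for i in range(3):
            assert abs(mu[i] - mc_mu[i]) < 3 * np.sqrt(Sigma[i, i] / n)
            for j in range(3):
                se = np.sqrt((Sigma[i, i] * Sigma[j, j] + Sigma[i, j] ** 2) / n)
                assert abs(Sigma[i, j] - mc_S[i, j]) < 3 * se

    def test_cyclic_block_raises(self):
        spec = ModelSpec(["a", "b"], ["a", "b"])
        spec.add_path("a", "b", value=1.0)
        spec.add_path("b", "a", value=1.0)
        spec.add_cov("a", "a", value=1.0)
        spec.add_cov("b", "b", value=1.0)
        with pytest.raises(np.linalg.LinAlgError, match="cyclic"):
            t.implied_moments(spec, np.zeros(0))


class TestFimlLoglik:
    def test_univariate_closed_form(self):
        y, mu, s2 = 1.7, 0.4, 2.3
        ll = t.fiml_loglik(np.array([[y]]), np.array([mu]), np.array([[s2]]))
        expect = -0.5 * (np.log(2 * np.pi) + np.log(s2) + (y - mu) ** 2 / s2)
        np.testing.assert_allclose(ll, expect)

    def test_saturated_identity_complete_data(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((40, 3)) @ np.diag([1.0, 2.0, 0.5])
        mu = vals.mean(axis=0)
        S = np.cov(vals.T, ddof=0)
        ll_at_moments = t.fiml_loglik(vals, mu, S)
        ll_sat = t.saturated_loglik(ObservedMatrix(vals, ["a", "b", "c"]))
        np.testing.assert_allclose(ll_at_moments, ll_sat, rtol=1e-10)
        # any other moments are worse
        assert t.fiml_loglik(vals, mu + 0.1, S) < ll_at_moments

    def test_marginalisation_of_missing_coordinates(self):
        mu = np.array([0.5, -1.0, 2.0])
        A = np.array([[1.0, 0.3, -0.2], [0.3, 2.0, 0.4], [-0.2, 0.4, 1.5]])
        row = np.array([[1.2, np.nan, 2.5]])
        ll = t.fiml_loglik(row, mu, A)
        sub = A[np.ix_([0, 2], [0, 2])]
        expect = stats.multivariate_normal(mu[[0, 2]], sub).logpdf([1.2, 2.5])
        np.testing.assert_allclose(ll, expect)

    def test_all_missing_rows_contribute_zero(self):
        mu = np.zeros(2)
        S = np.eye(2)
        full = np.array([[1.0, 0.5]])
        padded = np.array([[1.0, 0.5], [np.nan, np.nan]])
        np.testing.assert_allclose(t.fiml_loglik(full, mu, S),
                                   t.fiml_loglik(padded, mu, S))

    def test_non_pd_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            t.fiml_loglik(np.array([[0.0, 0.0]]), np.zeros(2),
                          np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestFitModel:
    def test_saturated_fit_reproduces_sample_moments(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal((200, 4)) + [1, 2, 3, 4]
        data = ObservedMatrix(vals, list("abcd"))
        fit = t.fit_model(_saturated_spec(list("abcd")), data,
                          compute_se=False, compute_indices=False,
                          _allow_sat=True)
        np.testing.assert_allclose(fit.implied_mu, vals.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(fit.implied_Sigma, np.cov(vals.T, ddof=0),
                                   atol=1e-6)
        assert fit.df == 0

    def test_two_wave_clpm_parameter_recovery(self):
        # 2 traits x 2 waves, cross-lag 0.3, n = 4000 individuals
        rng = np.random.default_rng(31)
        n = 4000
        x1 = rng.standard_normal(n)
        y1 = 0.2 * x1 + rng.standard_normal(n) * np.sqrt(0.96)
        x2 = 0.4 * x1 + rng.standard_normal(n) * np.sqrt(0.5)
        y2 = 0.3 * x1 + 0.4 * y1 + rng.standard_normal(n) * np.sqrt(0.5)
        spec = t.build_clpm(2, 2, traits=("x", "y"), occasions=(1, 2))
        data = ObservedMatrix(np.column_stack([x1, y1, x2, y2]),
                              ["x1", "y1", "x2", "y2"])
        fit = t.fit_model(spec, data, compute_se=False, compute_indices=False)
        assert fit.converged
        assert abs(fit.estimates["b_x1_to_y2"] - 0.3) < 0.05

    def test_all_fixed_evaluates_without_optimisation(self):
        spec = ModelSpec(["x"], ["x"])
        spec.add_cov("x", "x", value=1.0)
        spec.add_mean("x", value=0.0)
        vals = np.array([[0.3], [-0.6]])
        fit = t.fit_model(spec, ObservedMatrix(vals, ["x"]),
                          compute_se=False, compute_indices=False)
        assert fit.n_params == 0
        assert fit.df == spec.n_moments()
        np.testing.assert_allclose(fit.loglik,
                                   t.fiml_loglik(vals, np.zeros(1), np.eye(1)))

    def test_fiml_equals_complete_data_ml(self, medium_table):
        # with nothing missing, FIML == ML on the sample moments (saturated)
        data = t.to_observed_matrix(medium_table, "individual")
        assert not np.isnan(data.values).any()
        fit = t.fit_model(t.build_clpm(3, 3), data,
                          compute_se=False, compute_indices=False)
        # independent oracle: per-equation OLS for the recursive system
        import pandas as pd
        df = pd.DataFrame(data.values, columns=data.columns)
        X = np.column_stack([np.ones(len(df)), df["mp9"], df["ep9"], df["bp9"]])
        for target in ("mp12", "ep12", "bp12"):
            beta = np.linalg.lstsq(X, df[target], rcond=None)[0]
            for src, b in zip(("mp9", "ep9", "bp9"), beta[1:]):
                assert abs(fit.estimates[f"b_{src}_to_{target}"] - b) < 1e-4

    def test_likelihood_invariant_to_variable_reordering(self, small_table):
        data = t.to_observed_matrix(small_table, "individual")
        spec = t.build_clpm(3, 3)
        fit = t.fit_model(spec, data, compute_se=False, compute_indices=False)
        perm = np.random.default_rng(0).permutation(9)
        cols = [data.columns[i] for i in perm]
        data2 = ObservedMatrix(data.values[:, perm], cols)
        spec2 = ModelSpec(cols, cols)
        spec2.A_labels = {(cols.index(spec.variables[i]), cols.index(spec.variables[j])): lab
                          for (i, j), lab in spec.A_labels.items()}
        spec2.S_labels = {tuple(sorted((cols.index(spec.variables[i]),
                                        cols.index(spec.variables[j])))): lab
                          for (i, j), lab in spec.S_labels.items()}
        spec2.m_labels = {cols.index(spec.variables[i]): lab
                          for i, lab in spec.m_labels.items()}
        spec2.start_frac = spec.start_frac
        fit2 = t.fit_model(spec2, data2, compute_se=False, compute_indices=False)
        np.testing.assert_allclose(fit.loglik, fit2.loglik, rtol=1e-8)

    def test_equality_constraints_share_one_estimate(self, medium_table):
        data = t.to_observed_matrix(medium_table, "pair")
        fit = t.fit_model(t.build_riclpm_pair(3, 3), data,
                          compute_se=False, compute_indices=False)
        # equated label appears once; implied A entries for both twins equal
        comp = fit._comp
        A, S, mv = comp.matrices(fit._theta)
        spec = fit.spec
        i1 = spec.ix("w_mp12_t1"), spec.ix("w_bp9_t1")
        i2 = spec.ix("w_mp12_t2"), spec.ix("w_bp9_t2")
        assert A[i1] == A[i2]

    def test_mismatched_manifest_rejected(self, small_table):
        data = t.to_observed_matrix(small_table, "individual")
        with pytest.raises(ValueError, match="manifest"):
            t.fit_model(t.build_riclpm_pair(3, 3), data)


@pytest.fixture(scope="module")
def reg_fit():
    rng = np.random.default_rng(77)
    n = 4000
    x = rng.standard_normal(n)
    y = 0.5 * x + rng.standard_normal(n)
    data = ObservedMatrix(np.column_stack([x, y]), ["x", "y"])
    return t.fit_model(_regression_spec(), data, compute_indices=False), data


class TestRobustSE:

    def test_sandwich_close_to_naive_when_correct(self, reg_fit):
        fit, _ = reg_fit
        ratio = fit.params["robust_se"] / fit.params["naive_se"]
        assert ((ratio - 1).abs() < 0.15).all()

    def test_duplication_scaling_law(self, reg_fit):
        fit, data = reg_fit
        doubled = ObservedMatrix(np.vstack([data.values, data.values]),
                                 data.columns)
        fit2 = t.fit_model(_regression_spec(), doubled, compute_indices=False)
        ratio = fit2.params["robust_se"] / fit.params["robust_se"]
        np.testing.assert_allclose(ratio, 1 / np.sqrt(2), rtol=0.02)

    def test_heavy_tails_inflate_variance_parameter_se(self):
        rng = np.random.default_rng(8)
        n = 3000
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_t(3, n) / np.sqrt(3.0)
        data = ObservedMatrix(np.column_stack([x, y]), ["x", "y"])
        fit = t.fit_model(_regression_spec(), data, compute_indices=False)
        assert fit.params.loc["vy", "robust_se"] > \
            1.5 * fit.params.loc["vy", "naive_se"]


class TestStandardize:
    def test_unit_variance_leaves_paths_unscaled(self):
        spec = _regression_spec()
        data_rng = np.random.default_rng(3)
        x = data_rng.standard_normal(5000)
        y = 0.5 * x + data_rng.standard_normal(5000) * np.sqrt(0.75)
        # x and y both have implied variance ~1
        fit = t.fit_model(_regression_spec(),
                          ObservedMatrix(np.column_stack([x, y]), ["x", "y"]),
                          compute_indices=False)
        b, std = fit.params.loc["b", ["estimate", "std"]]
        sd_x = np.sqrt(fit.implied_Sigma[0, 0])
        sd_y = np.sqrt(fit.implied_Sigma[1, 1])
        np.testing.assert_allclose(std, b * sd_x / sd_y, rtol=1e-8)
        assert abs(std - b) < 0.05  # near-unit variances

    def test_hand_rescaling(self):
        # b = 0.06 with SD(x) = 1.86, SD(y) = 1.52 -> beta ~ 0.073
        spec = ModelSpec(["x", "y"], ["x", "y"])
        spec.add_cov("x", "x", value=1.86 ** 2)
        spec.add_cov("y", "y", value=1.52 ** 2 - (0.06 * 1.86) ** 2)
        spec.add_path("x", "y", value=0.06)
        mu, Sigma = t.implied_moments(spec, np.zeros(0))
        std = 0.06 * np.sqrt(Sigma[0, 0]) / np.sqrt(Sigma[1, 1])
        np.testing.assert_allclose(std, 0.06 * 1.86 / 1.52, rtol=1e-10)

    def test_covariance_standardises_to_correlation(self, small_table):
        data = t.to_observed_matrix(small_table, "individual")
        fit = t.fit_model(t.build_clpm(3, 3), data, compute_indices=False)
        v1 = fit.implied_Sigma[0, 0]
        v2 = fit.implied_Sigma[1, 1]
        cov = fit.estimates["c_mp9_ep9"]
        np.testing.assert_allclose(fit.params.loc["c_mp9_ep9", "std"],
                                   cov / np.sqrt(v1 * v2), rtol=1e-6)


class TestChiSquareProperty:
    def test_chi2_nonnegative_and_df_consistent(self, small_table):
        data = t.to_observed_matrix(small_table, "individual")
        fit = t.fit_model(t.build_clpm(3, 3), data, compute_se=False)
        assert fit.chi2 >= 0
        assert fit.df == 9
        np.testing.assert_allclose(
            fit.chi2, 2 * (fit.loglik_sat - fit.loglik), atol=1e-6)
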