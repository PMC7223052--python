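"""ML estimation of the second-order factor model.

Covers the covariance algebra, the discrepancy function, fit indices,
parameter recovery, and equivalence with an independently coded naive
fit (see oracles.py).
"""

import numpy as np
import pytest

import pwbi
from pwbi.model import ModelSpec
from pwbi.sem import (
    ParameterSet,
    fit,
    fit_indices,
    implied_covariance,
    ml_discrepancy,
    standardize,
)

from .oracles import naive_second_order_fit


def make_params(spec, lam, beta, theta=None):
    lam = {j: lam for j in spec.indicators} if np.isscalar(lam) else lam
    beta = {k: beta for k in spec.factors} if np.isscalar(beta) else beta
    if theta is None:
        theta = {j: 1.0 - lam[j] ** 2 for j in spec.indicators}
    elif np.isscalar(theta):
        theta = {j: theta for j in spec.indicators}
    return ParameterSet(
        loadings=lam, residuals=theta, betas=beta,
        psis={k: 1.0 - beta[k] ** 2 for k in spec.factors},
    )


class TestImpliedCovariance:
    def test_zero_loadings_give_diagonal_theta(self, spec):
        params = make_params(spec, 0.0, 0.0, 0.7)
        Sigma = implied_covariance(params, spec)
        assert np.allclose(Sigma, 0.7 * np.eye(len(spec.indicators)))

    def test_perfect_collinearity_gives_all_ones(self):
        spec = ModelSpec({"a": "L", "b": "S", "c": "E", "d": "MS"})
        params = make_params(spec, 1.0, 1.0, 0.0)
        Sigma = implied_covariance(params, spec)
        assert np.allclose(Sigma, np.ones((4, 4)))

    def test_matches_monte_carlo_draws(self, default_params, spec, true_params):
        """Closed-form Sigma vs the raw (pre-discretisation) latent draws."""
        from pwbi.cohort import latent_indicator_draws

        rng = np.random.default_rng(123)
        _, x = latent_indicator_draws(default_params, 100_000, rng, spec)
        sds = np.array([default_params.indicator_sds[j] for j in spec.indicators])
        S_hat = np.cov((x / sds), rowvar=False)
        Sigma = implied_covariance(true_params, spec)
        assert np.abs(S_hat - Sigma).max() < 0.03

    def test_symmetric_positive_definite(self, true_params, spec):
        Sigma = implied_covariance(true_params, spec)
        assert np.allclose(Sigma, Sigma.T)
        assert np.linalg.eigvalsh(Sigma).min() > 0


class TestMlDiscrepancy:
    def test_zero_at_equality(self, true_params, spec):
        Sigma = implied_covariance(true_params, spec)
        assert ml_discrepancy(Sigma, Sigma) == pytest.approx(0.0, abs=1e-12)

    def test_one_by_one_closed_form(self):
        # F = ln 1 + 2/1 - ln 2 - 1 = 1 - ln 2
        F = ml_discrepancy(np.array([[2.0]]), np.array([[1.0]]))
        assert F == pytest.approx(1.0 - np.log(2.0), abs=1e-12)

    def test_eigenvalue_form_identity(self):
        """F equals sum(mu - ln mu - 1) over eigenvalues of S Sigma^-1."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            A = rng.standard_normal((6, 6))
            S = A @ A.T + 6 * np.eye(6)
            B = rng.standard_normal((6, 6))
            Sigma = B @ B.T + 6 * np.eye(6)
            mu = np.linalg.eigvals(np.linalg.solve(Sigma, S)).real
            expected = float(np.sum(mu - np.log(mu) - 1.0))
            assert ml_discrepancy(S, Sigma) == pytest.approx(expected, abs=1e-10)

    def test_nonnegative(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((4, 4))
        S = A @ A.T + 4 * np.eye(4)
        assert ml_discrepancy(S, np.eye(4)) >= 0

    def test_singular_input_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            ml_discrepancy(np.ones((2, 2)), np.eye(2))


class TestFitIndices:
    def test_chi_square_equal_df_is_perfect(self):
        S = np.eye(3)
        rmsea, cfi, srmr = fit_indices(71.0, 71, 1248, 500.0, 3, S, S)
        assert rmsea == 0.0
        assert cfi == 1.0
        assert srmr == 0.0

    def test_rmsea_closed_form(self):
        S = np.eye(3)
        rmsea, _, _ = fit_indices(200.0, 71, 1248, 500.0, 3, S, S)
        assert rmsea == pytest.approx(np.sqrt(129.0 / (71 * 1247)), abs=1e-12)

    def test_srmr_diagonal_switch(self):
        S = np.eye(2)
        Sigma = np.array([[0.9, 0.1], [0.1, 0.9]])
        _, _, with_diag = fit_indices(10, 1, 100, 50, 1, S, Sigma)
        _, _, off_only = fit_indices(10, 1, 100, 50, 1, S, Sigma,
                                     srmr_diagonal=False)
        assert with_diag == pytest.approx(np.sqrt((0.01 + 0.01 + 0.01) / 3))
        assert off_only == pytest.approx(0.1)

    def test_df_must_be_positive(self):
        with pytest.raises(ValueError):
            fit_indices(10, 0, 100, 50, 1, np.eye(2), np.eye(2))


class TestStandardize:
    def test_identity_on_standardized_input(self, true_params, spec):
        out = standardize(true_params, spec=spec)
        for j in spec.indicators:
            assert out.loadings[j] == pytest.approx(true_params.loadings[j])

    def test_unstandardized_loading_rescaled(self):
        spec = ModelSpec({"a": "L", "b": "S", "c": "E"})
        params = ParameterSet(
            loadings={"a": 2.0, "b": 1.0, "c": 1.0},
            residuals={"a": 1e-12, "b": 0.5, "c": 0.5},
            betas={k: 0.5 for k in spec.factors},
            psis={k: 0.75 for k in spec.factors},
        )
        out = standardize(params, spec=spec)
        assert out.loadings["a"] == pytest.approx(1.0)  # sd(a) = 2, factor var 1

    def test_standardized_implied_equals_cov2cor(self, spec):
        rng = np.random.default_rng(5)
        lam = {j: rng.uniform(0.2, 0.9) * rng.uniform(1, 3) for j in spec.indicators}
        theta = {j: rng.uniform(0.3, 2.0) for j in spec.indicators}
        beta = {k: rng.uniform(0.2, 0.9) for k in spec.factors}
        params = ParameterSet(
            loadings=lam, residuals=theta, betas=beta,
            psis={k: 1 - beta[k] ** 2 for k in spec.factors},
        )
        Sigma = implied_covariance(params, spec)
        d = np.sqrt(np.diag(Sigma))
        cov2cor = Sigma / np.outer(d, d)
        Sigma_std = implied_covariance(standardize(params, spec=spec), spec)
        assert np.allclose(Sigma_std, cov2cor, atol=1e-10)

    def test_zero_variance_indicator_rejected(self, spec):
        params = make_params(spec, 0.0, 0.5, 0.0)
        with pytest.raises(ValueError):
            standardize(params, spec=spec)


class TestFit:
    def test_zero_discrepancy_recovery(self, true_params, spec):
        """Fitting the exact implied covariance returns the generating
        standardized parameters to 1e-4."""
        Sigma = implied_covariance(true_params, spec)
        est, res = fit(Sigma, 10_000, spec)
        assert res.converged
        assert res.chi_square == pytest.approx(0.0, abs=1e-6)
        for j in spec.indicators:
            assert est.loadings[j] == pytest.approx(true_params.loadings[j], abs=1e-4)
        for k in spec.factors:
            assert est.betas[k] == pytest.approx(true_params.betas[k], abs=1e-4)

    def test_degrees_of_freedom(self, fitted_1248, spec):
        _, res = fitted_1248
        p = len(spec.indicators)
        assert res.df == p * (p + 1) // 2 - res.n_free
        assert res.n_free == 2 * p + len(spec.factors)
        assert res.df_baseline == p * (p - 1) // 2

    def test_standard_errors_plausible(self, fitted_1248, spec):
        _, res = fitted_1248
        for k in ("L", "S", "E"):
            assert 0.005 < res.se[f"beta:{k}"] < 0.1

    def test_recovery_bias_over_replicates(self, default_params, spec):
        """Mean standardized beta over 50 study-sized replicates is within
        0.03 of the generating value for every component."""
        from .conftest import run_recovery

        betas = run_recovery(default_params, spec, n_reps=50, n=1248, seed0=100)
        for k in spec.factors:
            bias = betas[k].mean() - default_params.second_order_loadings[k]
            assert abs(bias) < 0.03, (k, bias)

    def test_indicator_rescaling_invariance(self, indicators_1248, spec):
        """Multiplying an indicator by a positive constant leaves the
        standardized solution and all fit indices unchanged."""
        est1, res1 = pwbi.fit_from_data(indicators_1248, spec)
        rescaled = indicators_1248.copy()
        rescaled["kidmed"] = rescaled["kidmed"] * 7.0
        rescaled["paqc"] = rescaled["paqc"] * 0.01
        est2, res2 = pwbi.fit_from_data(rescaled, spec)
        for j in spec.indicators:
            assert est2.loadings[j] == pytest.approx(est1.loadings[j], abs=1e-8)
        assert res2.chi_square == pytest.approx(res1.chi_square, abs=1e-8)
        assert res2.rmsea == pytest.approx(res1.rmsea, abs=1e-8)
        assert res2.srmr == pytest.approx(res1.srmr, abs=1e-8)

    def test_monotone_fit_under_constraint(self, indicators_1248, spec):
        """Freeing a constrained parameter never worsens the discrepancy."""
        _, free = pwbi.fit_from_data(indicators_1248, spec)
        _, constrained = pwbi.fit_from_data(
            indicators_1248, spec, fixed={"beta:MS": 0.0}
        )
        assert constrained.df == free.df + 1
        assert constrained.chi_square >= free.chi_square - 1e-6

    def test_heywood_case_reported_by_name(self):
        """A correlation pattern demanding negative residual variance pins
        theta at its bound and is flagged."""
        spec = ModelSpec({
            "a": "F1", "b": "F1", "c": "F1",
            "d": "F2", "e": "F2", "f": "F2",
            "g": "F3", "h": "F3", "i": "F3",
        })
        R = np.full((9, 9), 0.1)
        np.fill_diagonal(R, 1.0)
        # within-factor blocks
        for blk in ([0, 1, 2], [3, 4, 5], [6, 7, 8]):
            for a in blk:
                for b in blk:
                    if a != b:
                        R[a, b] = 0.3
        R[0, 1] = R[1, 0] = 0.7
        R[0, 2] = R[2, 0] = 0.7
        R[1, 2] = R[2, 1] = 0.25  # forces lambda_a^2 = .49/.25 = 1.96 > 1
        assert np.linalg.eigvalsh(R).min() > 0
        est, res = fit(R, 500, spec)
        assert "a" in res.heywood

    def test_input_validation(self, spec):
        with pytest.raises(ValueError):
            fit(np.eye(3), 100, spec)  # wrong dimension
        with pytest.raises(ValueError):
            fit(np.eye(len(spec.indicators)), 10, spec)  # n <= p
        with pytest.raises(np.linalg.LinAlgError):
            fit(np.ones((14, 14)), 100, spec)  # singular


class TestOracleEquivalence:
    def test_full_model_matches_naive_fit(self, default_params, spec):
        """On one fixed simulated dataset, the engine and an independently
        coded naive ML fit agree to 1e-3 (loadings) and 0.5 (chi-square)."""
        ind = pwbi.score_cohort(pwbi.generate_cohort(default_params, 1248, 42))
        est, res = pwbi.fit_from_data(ind, spec)
        X = ind[list(spec.indicators)].to_numpy(float)
        R = np.corrcoef(X, rowvar=False)
        lam, beta, theta, F = naive_second_order_fit(
            R, spec.indicator_map, list(spec.indicators), list(spec.factors)
        )
        for i, j in enumerate(spec.indicators):
            assert est.loadings[j] == pytest.approx(lam[i], abs=1e-3)
        for i, k in enumerate(spec.factors):
            assert est.betas[k] == pytest.approx(beta[i], abs=1e-3)
        assert res.chi_square == pytest.approx((1248 - 1) * F, abs=0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_small_random_models_match_naive_fit(self, seed):
        """Three factors x three indicators with random parameters: engine
        and naive oracle land on the same solution."""
        spec = ModelSpec({
            "a": "F1", "b": "F1", "c": "F1",
            "d": "F2", "e": "F2", "f": "F2",
            "g": "F3", "h": "F3", "i": "F3",
        })
        rng = np.random.default_rng(1000 + seed)
        lam = {j: rng.uniform(0.4, 0.8) for j in spec.indicators}
        beta = {k: rng.uniform(0.3, 0.9) for k in spec.factors}
        truth = make_params(spec, lam, beta)
        Sigma = implied_covariance(truth, spec)
        n = 400
        rng2 = np.random.default_rng(2000 + seed)
        X = rng2.multivariate_normal(np.zeros(9), Sigma, size=n)
        S = np.cov(X, rowvar=False)
        est, res = fit(S, n, spec)
        R = np.corrcoef(X, rowvar=False)
        lam_o, beta_o, _, F = naive_second_order_fit(
            R, spec.indicator_map, list(spec.indicators), list(spec.factors)
        )
        for i, j in enumerate(spec.indicators):
            assert est.loadings[j] == pytest.approx(lam_o[i], abs=1e-3)
        for i, k in enumerate(spec.factors):
            assert est.betas[k] == pytest.approx(beta_o[i], abs=1e-3)
        assert res.chi_square == pytest.approx((n - 1) * F, abs=0.5)
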