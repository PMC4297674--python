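import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

from freeknot.basis import SeparationError, bspline_basis, make_spline_spec
from freeknot.fitting import (
    FitConfig,
    ModelData,
    _irls,
    bernoulli_loglik,
    candidate_start_knots,
    fit_fixed_start,
    grid_search_fit,
    linear_logistic_start,
    weighted_loglik,
)


class TestWeightedLoglik:
    def test_even_odds_value(self):
        # eta = 0 for two subjects: log L = 2 log(0.5)
        assert bernoulli_loglik(np.zeros(2), np.array([0.0, 1.0]),
                                np.ones(2)) == pytest.approx(2 * np.log(0.5))

    def test_linear_in_weights(self):
        rng = np.random.default_rng(0)
        eta = rng.normal(size=50)
        y = (rng.random(50) < 0.5).astype(float)
        w = rng.uniform(0.5, 3.0, 50)
        assert bernoulli_loglik(eta, y, 2 * w) == pytest.approx(
            2 * bernoulli_loglik(eta, y, w))

    def test_matches_per_subject_sum(self):
        """Stabilized form equals the naive per-subject weighted sum."""
        rng = np.random.default_rng(1)
        n = 100
        x = rng.uniform(17, 45, n)
        y = (rng.random(n) < 0.4).astype(float)
        w = rng.uniform(0.2, 5.0, n)
        spec = make_spline_spec(x, (25.0, 32.0), 0.28)
        data = ModelData.from_arrays(y=y, x=x, weights=w)
        beta = np.array([-0.5])
        b = np.array([0.7, -0.3, 0.4])
        ll = weighted_loglik(beta, b, spec, data)
        eta = beta[0] + bspline_basis(x, spec) @ b
        pi = expit(eta)
        naive = np.sum(w * (y * np.log(pi) + (1 - y) * np.log(1 - pi)))
        assert ll == pytest.approx(naive, abs=1e-12)

    def test_extreme_eta_does_not_overflow(self):
        ll = bernoulli_loglik(np.array([500.0, -500.0]),
                              np.array([1.0, 0.0]), np.ones(2))
        assert np.isfinite(ll) and ll == pytest.approx(0.0, abs=1e-12)


class TestLinearLogisticStart:
    def test_null_association(self):
        rng = np.random.default_rng(2)
        n = 4000
        x = rng.uniform(0, 1, n)
        y = (rng.random(n) < 0.4).astype(float)
        coef = linear_logistic_start(ModelData.from_arrays(y=y, x=x))
        assert coef[-1] == pytest.approx(0.0, abs=0.3)
        assert coef[0] == pytest.approx(logit(y.mean()), abs=0.3)

    def test_recovers_known_slope(self):
        rng = np.random.default_rng(3)
        n = 5000
        x = rng.uniform(17, 45, n)
        eta = 1.0 - 0.1 * x
        y = (rng.random(n) < expit(eta)).astype(float)
        data = ModelData.from_arrays(y=y, x=x)
        coef = linear_logistic_start(data)
        # information-based SE of the slope
        X = np.column_stack([np.ones(n), x])
        mu = expit(X @ coef[[0, 1]])
        cov = np.linalg.inv(X.T @ ((mu * (1 - mu))[:, None] * X))
        se = np.sqrt(cov[1, 1])
        assert abs(coef[-1] - (-0.1)) < 2 * se

    def test_matches_statsmodels_weighted(self):
        """IRLS agrees with the standard GLM fit under sampling weights."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        n = 800
        x = rng.uniform(0, 2, n)
        z = rng.normal(size=n)
        y = (rng.random(n) < expit(-0.3 + 0.8 * x - 0.5 * z)).astype(float)
        w = rng.uniform(0.5, 4.0, n)
        data = ModelData.from_arrays(y=y, x=x, covariates=z, weights=w)
        ours = linear_logistic_start(data)
        X = np.column_stack([np.ones(n), z, x])
        ref = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit()
        assert ours == pytest.approx(ref.params, abs=1e-6)

    def test_separable_data_falls_back(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0])
        y = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.warns(UserWarning, match="separation|converge"):
            coef = linear_logistic_start(ModelData.from_arrays(y=y, x=x))
        assert np.all(coef == 0)


class TestFitFixedStart:
    def test_k0_matches_irls(self, small_dataset):
        data, _ = small_dataset
        fit = fit_fixed_start(data, [])
        X = np.column_stack([data.Z, bspline_basis(data.x, fit.spec)])
        coef, nll, ok = _irls(X, data.y, data.weights)
        assert ok and fit.converged
        assert fit.beta[0] == pytest.approx(coef[0], abs=1e-6)
        assert fit.spline_coefs[0] == pytest.approx(coef[1], abs=1e-6)
        assert fit.neg_loglik == pytest.approx(nll, abs=1e-8)

    def test_recovers_true_model_large_n(self):
        """K=2 fit from a nearby start recovers the U-shaped truth."""
        from freeknot import SimConfig, simulate_dataset
        data, _ = simulate_dataset(SimConfig(n=20_000, p0=0.33),
                                   np.random.default_rng(12))
        fit = fit_fixed_start(data, [24.0, 33.0])
        assert fit.converged
        assert fit.spec.knots[0] == pytest.approx(25.0, abs=1.0)
        assert fit.spec.knots[1] == pytest.approx(32.0, abs=1.0)
        pw = fit.to_piecewise()
        assert pw.slopes == pytest.approx((-0.4, 0.0, 0.2), abs=0.05)

    def test_too_close_start_knots_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 100)
        y = (rng.random(100) < 0.5).astype(float)
        data = ModelData.from_arrays(y=y, x=x)
        with pytest.raises(SeparationError):
            fit_fixed_start(data, [0.5, 0.501], FitConfig(min_separation=0.01))

    def test_parameter_count(self, small_dataset):
        data, _ = small_dataset
        fit = fit_fixed_start(data, [25.0, 32.0])
        assert fit.n_params == 0 + 2 * 2 + 2  # p + 2K + 2


class TestGridSearch:
    def test_k0_single_start(self, small_dataset):
        data, _ = small_dataset
        fit = grid_search_fit(data, 0)
        assert fit.n_starts == 1
        ref = fit_fixed_start(data, [])
        assert fit.neg_loglik == pytest.approx(ref.neg_loglik, abs=1e-9)

    def test_c_choose_k_starts(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1, 500)
        y = (rng.random(500) < 0.5).astype(float)
        data = ModelData.from_arrays(y=y, x=x)
        starts = candidate_start_knots(data, 2, FitConfig(grid_points=6))
        assert len(starts) == 15  # C(6, 2)

    def test_empty_segment_starts_skipped(self):
        # a hole in the predictor support removes combos straddling it
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.uniform(0, 0.3, 250), rng.uniform(0.9, 1.0, 250)])
        y = (rng.random(500) < 0.5).astype(float)
        data = ModelData.from_arrays(y=y, x=x)
        starts = candidate_start_knots(data, 2, FitConfig(grid_points=6))
        assert 0 < len(starts) < 15

    def test_monotone_improvement_with_k(self, small_dataset):
        data, _ = small_dataset
        f0 = grid_search_fit(data, 0)
        f1 = grid_search_fit(data, 1)
        assert f1.neg_loglik <= f0.neg_loglik + 1e-6

    def test_quasi_newton_matches_nelder_mead(self, small_dataset):
        """Profile optimum from the default optimizer vs a Nelder-Mead refit."""
        data, _ = small_dataset
        fit = grid_search_fit(data, 2)
        delta = FitConfig().resolve_separation(data.x)

        def profile_nll(knots):
            knots = np.sort(knots)
            if (np.any(np.diff(knots) < delta)
                    or knots[0] < data.x.min() + delta
                    or knots[-1] > data.x.max() - delta):
                return 1e10
            spec = make_spline_spec(data.x, knots, delta)
            X = np.column_stack([data.Z, bspline_basis(data.x, spec)])
            _, nll, _ = _irls(X, data.y, data.weights)
            return nll

        res = minimize(profile_nll, np.array(fit.spec.knots),
                       method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10})
        assert fit.neg_loglik == pytest.approx(res.fun, abs=1e-4)


class TestBasisEquivalence:
    def test_bspline_and_truncated_power_fits_agree(self, small_dataset):
        """Same function space: fixed-knot fits in either basis coincide."""
        from freeknot.basis import truncated_power_basis

        data, _ = small_dataset
        spec = make_spline_spec(data.x, (25.0, 32.0), 0.28)
        Xb = np.column_stack([data.Z, bspline_basis(data.x, spec)])
        Xt = np.column_stack([data.Z, truncated_power_basis(data.x, spec)])
        cb, nb, okb = _irls(Xb, data.y, data.weights)
        ct, nt, okt = _irls(Xt, data.y, data.weights)
        assert okb and okt
        assert nb == pytest.approx(nt, abs=1e-6)
        assert np.max(np.abs(Xb @ cb - Xt @ ct)) < 1e-4
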