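import numpy as np
import pytest

import freeknot.selection as sel_mod
from freeknot.fitting import ModelFit, grid_search_fit, make_spline_spec
from freeknot.selection import (
    KnotTestResult,
    SelectionConfig,
    aic,
    bic,
    bootstrap_knot_test,
    f_ratio,
    lr_statistic,
    select_by_ic,
    select_knots_forward,
    simulate_null_outcomes,
)


def _dummy_fit(neg_loglik, K=0, fingerprint=("d",)):
    spec = make_spline_spec(np.array([0.0, 1.0]),
                            tuple(np.linspace(0.2, 0.8, K)) if K else ())
    return ModelFit(spec=spec, beta=np.array([0.0]),
                    spline_coefs=np.zeros(K + 1), neg_loglik=neg_loglik,
                    converged=True, n_obs=100, data_fingerprint=fingerprint)


class TestLRStatistic:
    def test_identical_fits(self):
        assert lr_statistic(_dummy_fit(100.0), _dummy_fit(100.0, K=1)) == 0.0

    def test_arithmetic(self):
        assert lr_statistic(_dummy_fit(100.0), _dummy_fit(97.7, K=1)) == pytest.approx(2.3)

    def test_worse_alternative_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            lr = lr_statistic(_dummy_fit(100.0), _dummy_fit(101.0, K=1))
        assert lr == 0.0

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError):
            lr_statistic(_dummy_fit(1.0, fingerprint=("a",)),
                         _dummy_fit(0.5, K=1, fingerprint=("b",)))


class TestFRatio:
    def test_equal_sse_zero(self):
        assert f_ratio(100.0, 100.0, 500, 0, 2) == 0.0

    def test_worked_example(self):
        # (10/2) / (100/102) with df_full = 112 - (0 + 8 + 2) = 102
        assert f_ratio(110.0, 100.0, 112, 0, 4) == pytest.approx(5.1)

    def test_df_formula(self):
        # df_full = N - (p + 2K + 2); an SSE drop of 2*SSE_full/df gives F=1
        N, p, K = 500, 0, 2
        df = N - (p + 2 * K + 2)
        assert df == 494
        assert f_ratio(100 + 200 / df, 100.0, N, p, K) == pytest.approx(1.0)

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError):
            f_ratio(10.0, 5.0, 10, 0, 4)


class TestParametricResampling:
    def test_bernoulli_mean_matches_pi(self, flat_logistic_data):
        data, _ = flat_logistic_data
        fit = grid_search_fit(data, 0)
        pi = fit.predict_proba(data.x, data.Z)
        rng = np.random.default_rng(0)
        acc = np.zeros(data.n)
        R = 2000
        for _ in range(R):
            acc += simulate_null_outcomes(fit, data, rng)
        se = np.sqrt(pi * (1 - pi) / R)
        assert np.mean(np.abs(acc / R - pi) < 3 * se + 1e-9) > 0.99

    def test_deterministic_under_seed(self, flat_logistic_data):
        data, _ = flat_logistic_data
        fit = grid_search_fit(data, 0)
        a = simulate_null_outcomes(fit, data, np.random.default_rng(5))
        b = simulate_null_outcomes(fit, data, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_degenerate_probabilities(self, flat_logistic_data):
        data, _ = flat_logistic_data
        fit = grid_search_fit(data, 0)
        fit.beta = fit.beta - 1000.0  # drive pi to ~0
        fit.spline_coefs = np.zeros_like(fit.spline_coefs)
        y = simulate_null_outcomes(fit, data, np.random.default_rng(1))
        assert y.sum() == 0


class TestPBoot:
    def test_worked_case(self):
        # D1 = 19, one replicate at least as large: p = (1+1)/20
        assert sel_mod._p_boot(2.0, np.array([3.0] + [0.0] * 18)) == pytest.approx(0.10)

    def test_zero_observed_gives_one(self):
        assert sel_mod._p_boot(0.0, np.zeros(19)) == 1.0

    def test_bounds(self):
        reps = np.arange(19.0)
        assert 1 / 20 <= sel_mod._p_boot(100.0, reps) <= 1.0
        assert sel_mod._p_boot(100.0, reps) == pytest.approx(1 / 20)


class TestBootstrapKnotTest:
    def test_reproducible_and_bounded(self, flat_logistic_data):
        data, _ = flat_logistic_data
        cfg = SelectionConfig(alpha=0.10, D1=19)
        t1 = bootstrap_knot_test(data, 0, cfg, rng=3)
        t2 = bootstrap_knot_test(data, 0, cfg, rng=3)
        assert np.array_equal(t1.replicates, t2.replicates)
        assert t1.p_boot == t2.p_boot
        assert 1 / 20 <= t1.p_boot <= 1.0
        assert t1.p_boot == sel_mod._p_boot(t1.observed, t1.replicates)

    def test_order_invariant_parallel(self, flat_logistic_data):
        data, _ = flat_logistic_data
        cfg_serial = SelectionConfig(alpha=0.10, D1=19, n_jobs=1)
        cfg_par = SelectionConfig(alpha=0.10, D1=19, n_jobs=2)
        a = bootstrap_knot_test(data, 0, cfg_serial, rng=4)
        b = bootstrap_knot_test(data, 0, cfg_par, rng=4)
        assert np.array_equal(a.replicates, b.replicates)


class TestForwardSelection:
    def _patch_tests(self, monkeypatch, p_by_knull):
        def fake(data, K_null, config=None, rng=None, fit_null=None):
            p = p_by_knull[K_null]
            fit_n = _dummy_fit(100.0 - K_null, K=K_null)
            fit_a = _dummy_fit(99.0 - K_null, K=K_null + 1)
            return KnotTestResult(K_null, K_null + 1, 1.0, np.zeros(19), p,
                                  reject=p < config.alpha, alpha=config.alpha,
                                  fit_null=fit_n, fit_alt=fit_a)
        monkeypatch.setattr(sel_mod, "bootstrap_knot_test", fake)

    def test_stops_at_first_retained_null(self, monkeypatch):
        self._patch_tests(monkeypatch, {0: 0.01, 1: 0.02, 2: 0.50, 3: 0.01})
        res = select_knots_forward(None, SelectionConfig(alpha=0.10, D1=19))
        assert res.chosen_K == 2
        assert [t.K_null for t in res.tests] == [0, 1, 2]

    def test_all_reject_chooses_kmax(self, monkeypatch):
        self._patch_tests(monkeypatch, {k: 0.01 for k in range(4)})
        res = select_knots_forward(None, SelectionConfig(alpha=0.10, D1=19, Kmax=4))
        assert res.chosen_K == 4
        assert len(res.tests) == 4

    def test_immediate_retain_chooses_zero(self, monkeypatch):
        self._patch_tests(monkeypatch, {0: 0.90})
        res = select_knots_forward(None, SelectionConfig(alpha=0.10, D1=19))
        assert res.chosen_K == 0


class TestInformationCriteria:
    def test_aic_arithmetic(self):
        assert aic(_dummy_fit(50.0, K=1)) == pytest.approx(108.0)  # r = 4

    def test_bic_aic_crossover_at_e_squared(self):
        fit = _dummy_fit(50.0, K=1)
        fit.n_obs = int(round(np.e ** 2))  # log n ~ 2
        assert bic(fit) - aic(fit) == pytest.approx(
            fit.n_params * (np.log(fit.n_obs) - 2))

    def test_equal_likelihood_prefers_smaller_k(self, monkeypatch):
        fits = {K: _dummy_fit(100.0, K=K) for K in range(3)}
        monkeypatch.setattr(sel_mod, "grid_search_fit",
                            lambda data, K, config: fits[K])
        assert select_by_ic(None, "AIC", Kmax=2) == 0
        assert select_by_ic(None, "BIC", Kmax=2) == 0

    def test_penalty_wipe_out_under_raw_weights(self):
        """Huge survey weights swamp the AIC/BIC penalties: Kmax is chosen."""
        from freeknot import SimConfig, simulate_dataset
        data, _ = simulate_dataset(
            SimConfig(n=800, p0=0.33, weighted=True, mean_weight=1e4),
            np.random.default_rng(21))
        kA = select_by_ic(data, "AIC", Kmax=2)
        kB = select_by_ic(data, "BIC", Kmax=2)
        assert kA == 2 and kB == 2

    def test_normalized_weights_restore_penalty(self):
        """Rescaling weights to sum to n puts AIC back on a usable scale
        (same point estimates, penalty no longer wiped out)."""
        from freeknot import SimConfig, simulate_dataset
        data, _ = simulate_dataset(
            SimConfig(n=800, p0=0.33, weighted=True, mean_weight=1e4),
            np.random.default_rng(21))
        norm = data.with_normalized_weights()
        assert norm.weights.sum() == pytest.approx(norm.n)
        f_raw = grid_search_fit(data, 0)
        f_norm = grid_search_fit(norm, 0)
        scale = data.weights.sum() / norm.n
        assert f_raw.neg_loglik == pytest.approx(
            f_norm.neg_loglik * scale, rel=1e-6)
        assert f_raw.beta[0] == pytest.approx(f_norm.beta[0], abs=1e-4)

    def test_invalid_criterion(self):
        with pytest.raises(ValueError):
            select_by_ic(None, "DIC", Kmax=1)
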