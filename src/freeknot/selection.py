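"""Parametric-bootstrap 2-df forward knot selection, with AIC/BIC comparators.

Adding one knot adds two parameters (a knot location and a slope), hence the
"2 df" test.  Because free-knot models with K and K+1 knots are not nested,
the null distribution of the likelihood-ratio statistic is unknown; it is
built by a parametric bootstrap: simulate binary outcomes from the fitted
K-knot null model, refit both models on each replicate (full grid search,
as on the observed data), and compare the observed statistic against the
replicate distribution,

    p_boot = (1 + #{LR_rep >= LR_obs}) / (D1 + 1).

The forward procedure tests K=0 vs 1, 1 vs 2, ... and stops at the first
retained null; if every test up to Kmax-1 rejects, Kmax is chosen.

AIC and BIC are provided as comparators.  They are deliberately computed on
the raw weighted likelihood: with survey weights summing far beyond the
sample size the likelihood scale dwarfs the parameter penalties, which is
exactly the failure mode ("penalty wipe-out") the bootstrap test avoids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from scipy.special import expit

from .basis import PiecewiseModel
from .fitting import (
    FitConfig,
    GridSearchError,
    ModelData,
    ModelFit,
    fit_fixed_start,
    grid_search_fit,
)

__all__ = [
    "SelectionConfig",
    "KnotTestResult",
    "SelectionResult",
    "lr_statistic",
    "f_ratio",
    "simulate_null_outcomes",
    "bootstrap_knot_test",
    "select_knots_forward",
    "aic",
    "bic",
    "select_by_ic",
]


@dataclass
class SelectionConfig:
    """Settings of the forward bootstrap test.

    ``alpha`` is the significance-level selection criterion; smaller alpha
    yields fewer knots.  ``D1`` is the parametric-bootstrap replicate count
    (200 is a workable default; 1000 for publication-grade runs).
    ``warm_start_replicates`` restarts replicate fits from the observed-data
    knots only (cheaper, not the default: the reference procedure re-runs
    the full grid search on every replicate).
    """

    alpha: float = 0.10
    D1: int = 200
    Kmax: int = 4
    fit: FitConfig = field(default_factory=FitConfig)
    warm_start_replicates: bool = False
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.D1 < 19:
            raise ValueError("D1 must be at least 19")


@dataclass
class KnotTestResult:
    """One 2-df test of K_null vs K_null + 1 knots."""

    K_null: int
    K_alt: int
    observed: float
    replicates: np.ndarray
    p_boot: float
    reject: bool
    alpha: float
    fit_null: ModelFit | None = None
    fit_alt: ModelFit | None = None
    n_failed_replicates: int = 0


@dataclass
class SelectionResult:
    """Outcome of the forward procedure: chain of tests and the final model."""

    chosen_K: int
    tests: list
    final_fit: ModelFit
    final_piecewise: PiecewiseModel


def lr_statistic(fit_null: ModelFit, fit_alt: ModelFit) -> float:
    """LR = (-log L_null) - (-log L_alt), clamped at zero.

    A negative difference can occur because the models are non-nested; it is
    clamped to 0 with a warning so the bootstrap p-value stays well defined.
    """
    if fit_null.data_fingerprint != fit_alt.data_fingerprint:
        raise ValueError("fits were not computed on the same data")
    lr = fit_null.neg_loglik - fit_alt.neg_loglik
    if lr < 0:
        warnings.warn(
            f"alternative ({fit_alt.K} knots) fit worse than null "
            f"({fit_null.K} knots); LR {lr:.3g} clamped to 0", stacklevel=2)
        return 0.0
    return float(lr)


def f_ratio(sse_reduced: float, sse_full: float, N: int, p: int, K: int) -> float:
    """The 2-df F-ratio of the least-squares variant of the test.

    ``df_full = N - (p + 2K + 2)``: sample size minus the free parameters of
    the full model.  Exposed as a statistic only; model fitting in this
    package is likelihood-based.
    """
    if sse_reduced < 0 or sse_full < 0:
        raise ValueError("SSE values must be non-negative")
    df_full = N - (p + 2 * K + 2)
    if df_full <= 0:
        raise ValueError(f"non-positive df_full = {df_full}")
    return ((sse_reduced - sse_full) / 2.0) / (sse_full / df_full)


def simulate_null_outcomes(fit_null: ModelFit, data: ModelData,
                           rng: np.random.Generator) -> np.ndarray:
    """Parametric-bootstrap outcomes: ``y* ~ Bernoulli(pi_hat)`` at the null
    fit, holding predictor, covariates and weights fixed."""
    pi = fit_null.predict_proba(data.x, data.Z)
    return (rng.random(data.n) < pi).astype(float)


def _p_boot(observed: float, replicates: np.ndarray) -> float:
    D1 = len(replicates)
    return (1.0 + float(np.sum(replicates >= observed))) / (D1 + 1.0)


def _fit_pair(data: ModelData, K_null: int, config: SelectionConfig,
              warm_knots: tuple | None = None):
    """Fit the K_null and K_null+1 models, optionally warm-started."""
    if warm_knots is not None:
        null_knots, alt_knots = warm_knots
        fn = fit_fixed_start(data, null_knots, config.fit)
        fa = fit_fixed_start(data, alt_knots, config.fit)
        return fn, fa
    fn = grid_search_fit(data, K_null, config.fit)
    fa = grid_search_fit(data, K_null + 1, config.fit)
    return fn, fa


def _replicate_lr(seed_seq, data: ModelData, fit_null: ModelFit, K_null: int,
                  config: SelectionConfig, warm_knots):
    """One parametric-bootstrap replicate LR; redraw on failure (max 3)."""
    for attempt, child in enumerate(seed_seq.spawn(3)):
        rng = np.random.default_rng(child)
        y_star = simulate_null_outcomes(fit_null, data, rng)
        rep = data.with_outcomes(y_star)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fn, fa = _fit_pair(rep, K_null, config, warm_knots)
                return lr_statistic(fn, fa), attempt
        except GridSearchError:
            continue
    return 0.0, -1  # all attempts failed; count as statistic 0


def bootstrap_knot_test(data: ModelData, K_null: int,
                        config: SelectionConfig | None = None,
                        rng=None, fit_null: ModelFit | None = None) -> KnotTestResult:
    """The parametric-bootstrap 2-df test of K_null vs K_null + 1 knots.

    ``rng`` may be an int seed, a ``numpy.random.SeedSequence`` or a
    Generator; each replicate draws from its own spawned seed so results are
    reproducible and invariant to execution order (replicates may run in
    parallel via ``config.n_jobs``).
    """
    config = config or SelectionConfig()
    ss = _as_seedseq(rng)
    if fit_null is None:
        fit_null = grid_search_fit(data, K_null, config.fit)
    fit_alt = grid_search_fit(data, K_null + 1, config.fit)
    observed = lr_statistic(fit_null, fit_alt)
    warm = (fit_null.spec.knots, fit_alt.spec.knots) \
        if config.warm_start_replicates else None
    children = ss.spawn(config.D1)
    results = Parallel(n_jobs=config.n_jobs)(
        delayed(_replicate_lr)(c, data, fit_null, K_null, config, warm)
        for c in children)
    reps = np.array([r[0] for r in results])
    n_failed = sum(1 for r in results if r[1] == -1)
    if n_failed:
        warnings.warn(f"{n_failed} replicate(s) failed all fit attempts; "
                      "counted as statistic 0", stacklevel=2)
    p = _p_boot(observed, reps)
    return KnotTestResult(K_null, K_null + 1, observed, reps, p,
                          reject=p < config.alpha, alpha=config.alpha,
                          fit_null=fit_null, fit_alt=fit_alt,
                          n_failed_replicates=n_failed)


def _as_seedseq(rng) -> np.random.SeedSequence:
    if isinstance(rng, np.random.SeedSequence):
        return rng
    if isinstance(rng, np.random.Generator):
        return np.random.SeedSequence(int(rng.integers(2 ** 31)))
    return np.random.SeedSequence(rng)


def select_knots_forward(data: ModelData, config: SelectionConfig | None = None,
                         rng=None) -> SelectionResult:
    """Forward 2-df selection: stop at the first retained null.

    Chooses the first ``K`` whose test retains the null hypothesis; if every
    test up to ``Kmax - 1`` rejects, chooses ``Kmax`` and stops.
    """
    config = config or SelectionConfig()
    ss = _as_seedseq(rng)
    tests = []
    fit_null = None
    test_seeds = ss.spawn(config.Kmax)
    for K in range(config.Kmax):
        t = bootstrap_knot_test(data, K, config, rng=test_seeds[K],
                                fit_null=fit_null)
        tests.append(t)
        if not t.reject:
            final = t.fit_null
            return SelectionResult(K, tests, final, final.to_piecewise())
        fit_null = t.fit_alt  # the alt of this test is the null of the next
    final = tests[-1].fit_alt
    return SelectionResult(config.Kmax, tests, final, final.to_piecewise())


# ---------------------------------------------------------------------------
# information criteria

def aic(fit: ModelFit) -> float:
    """AIC = -2 log L + 2 r with r = p + 2K + 2, on the raw weighted likelihood."""
    return 2.0 * fit.neg_loglik + 2.0 * fit.n_params


def bic(fit: ModelFit) -> float:
    """BIC = -2 log L + r log(n); n is the sample size, not the weight sum."""
    return 2.0 * fit.neg_loglik + fit.n_params * np.log(fit.n_obs)


def select_by_ic(data: ModelData, criterion: str = "AIC", Kmax: int = 4,
                 config: FitConfig | None = None,
                 return_fits: bool = False):
    """Grid-search-fit K = 0..Kmax and return the argmin of the criterion.

    Ties break toward the smaller K (the penalty is monotone in r, so exact
    likelihood ties resolve to the simpler model).
    """
    crit = {"AIC": aic, "BIC": bic}.get(criterion.upper())
    if crit is None:
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    config = config or FitConfig()
    fits, scores = {}, {}
    for K in range(Kmax + 1):
        try:
            fits[K] = grid_search_fit(data, K, config)
        except GridSearchError as err:
            if err.best_fit is None:
                raise
            fits[K] = err.best_fit
        scores[K] = crit(fits[K])
    best = min(scores, key=lambda K: (round(scores[K], 9), K))
    if return_fits:
        return best, fits, scores
    return best
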