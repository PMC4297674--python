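"""Design-based uncertainty for a chosen-K model.

Replicate estimates come from refitting the chosen model on Rao–Wu PSU
bootstrap resamples of the survey design.  Intervals are bootstrap-t: the
studentized pivot ``T_i* = (theta_i* - theta_hat) / se_i*`` is bootstrapped
(each replicate brings its own standard error from the observed-information
matrix at its optimum), empirical equal-tail critical values are read off
the ordered ``T*`` distribution, and the interval is

    ( theta_hat - T*_(upper) * se_hat,  theta_hat - T*_(lower) * se_hat ).

The pivot distribution need not be symmetric, so neither is the interval.
All inference is reported on the piecewise parameterization — knots, local
slopes, intercept and covariate coefficients — the form users interpret.

Odds ratios compare two predictor values through the spline part of the
log-odds only: ``OR(x1, x2) = exp(s(x1) - s(x2))``, which is free of the
covariates, so the same curve applies to otherwise-similar individuals at
any covariate setting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import PiecewiseModel, SplineSpec, piecewise_eval
from .fitting import (
    FitConfig,
    FitError,
    ModelData,
    ModelFit,
    bernoulli_loglik,
    fit_fixed_start,
)
from .survey import rao_wu_resample

__all__ = [
    "BootstrapInference",
    "piecewise_param_names",
    "piecewise_param_vector",
    "piecewise_negloglik",
    "observed_information",
    "psu_bootstrap_fit",
    "bootstrap_t_ci",
    "bootstrap_inference",
    "odds_ratio",
    "or_curve",
]


def piecewise_param_names(K: int, p: int) -> list[str]:
    names = ["a0"] + [f"slope_{i}" for i in range(1, K + 2)]
    names += [f"knot_{i}" for i in range(1, K + 1)]
    names += [f"beta_{i}" for i in range(1, p + 1)]
    return names


def piecewise_param_vector(fit: ModelFit) -> np.ndarray:
    """Flatten a fit into (a0, slopes, knots, covariate betas)."""
    pw = fit.to_piecewise()
    return np.concatenate([[pw.intercept], pw.slopes, fit.spec.knots,
                           fit.beta[1:]])


def _unpack(theta: np.ndarray, K: int, p: int, base_spec: SplineSpec):
    a0 = theta[0]
    slopes = theta[1:K + 2]
    knots = theta[K + 2:2 * K + 2]
    betas = theta[2 * K + 2:]
    spec = SplineSpec(base_spec.lower, base_spec.upper,
                      tuple(float(z) for z in np.sort(knots)), 0.0)
    return PiecewiseModel(spec, float(a0), tuple(float(s) for s in slopes)), betas


def piecewise_negloglik(theta: np.ndarray, data: ModelData, K: int,
                        base_spec: SplineSpec) -> float:
    """Negative weighted log-likelihood as a function of piecewise parameters."""
    pw, betas = _unpack(np.asarray(theta, float), K, data.p, base_spec)
    eta = piecewise_eval(pw, data.x)
    if data.p:
        eta = eta + data.Z[:, 1:] @ betas
    return -bernoulli_loglik(eta, data.y, data.weights)


def observed_information(fit: ModelFit, data: ModelData,
                         step_scale: float = 1e-5):
    """Finite-difference observed-information matrix on the piecewise
    parameterization at the fitted optimum.

    Returns ``(info, cov, se, log10_condition)``.  The covariance is the
    (pseudo-)inverse of the information; a large condition number signals a
    flat likelihood direction (e.g. a knot in a data-sparse region) and is
    reported rather than hidden.
    """
    theta = piecewise_param_vector(fit)
    K = fit.K
    d = theta.size
    h = step_scale * np.maximum(1.0, np.abs(theta))
    f0 = piecewise_negloglik(theta, data, K, fit.spec)

    def f(t):
        return piecewise_negloglik(t, data, K, fit.spec)

    H = np.empty((d, d))
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        e = np.zeros(d); e[i] = h[i]
        fp[i] = f(theta + e)
        fm[i] = f(theta - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            fpp = f(theta + ei + ej)
            fmm = f(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j]
                                 + fmm) / (2 * h[i] * h[j])
    sym = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(sym)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(sym)
    eig = np.linalg.eigvalsh(sym)
    cond = np.log10(max(abs(eig[-1]), 1e-300) / max(abs(eig[0]), 1e-300))
    diag = np.diag(cov).copy()
    bad = diag <= 0
    if bad.any():
        diag[bad] = np.nan
    return sym, cov, np.sqrt(diag), float(cond)


@dataclass
class BootstrapInference:
    """PSU-bootstrap replicate table, Eq.-(21)-style SEs, and bootstrap-t CIs.

    ``replicates`` holds one row per usable replicate on the piecewise
    parameterization; ``boot_se`` is the replicate standard deviation around
    the point estimate's mean (the design-based SE); ``ci`` has columns
    lower/upper at ``level``.
    """

    names: list
    estimates: np.ndarray
    point_se: np.ndarray
    replicates: pd.DataFrame
    replicate_se: pd.DataFrame
    boot_se: np.ndarray
    ci: pd.DataFrame
    level: float
    D2: int
    n_dropped: int
    boundary_flag_rate: float
    replicate_cov: np.ndarray | None = None
    point_cov: np.ndarray | None = None

    def table(self) -> pd.DataFrame:
        t = pd.DataFrame({"estimate": self.estimates, "se_boot": self.boot_se,
                          "lower": self.ci["lower"], "upper": self.ci["upper"]},
                         index=self.names)
        bad = (t["lower"] > t["estimate"]) | (t["upper"] < t["estimate"])
        if bad.any():
            warnings.warn(
                f"bootstrap-t interval excludes the point estimate for "
                f"{list(t.index[bad])}", stacklevel=2)
        return t


def psu_bootstrap_fit(data: ModelData, chosen_fit: ModelFit, D2: int = 1000,
                      config: FitConfig | None = None, rng=None,
                      store_cov: bool = False):
    """Refit the chosen-K model on ``D2`` Rao–Wu resamples.

    Each replicate is warm-started at the chosen fit's knots, recorded on
    the piecewise parameterization, and paired with an observed-information
    SE at its own optimum.  Non-converging replicates are dropped and
    logged; losing more than 10% triggers a hard warning.  Replicates whose
    knots sit within the minimum separation of a boundary are kept but
    flagged.
    """
    if data.design is None:
        raise FitError("PSU bootstrap requires a survey design")
    config = config or FitConfig()
    ss = np.random.SeedSequence(rng) if not isinstance(
        rng, np.random.SeedSequence) else rng
    K, p = chosen_fit.K, data.p
    names = piecewise_param_names(K, p)
    delta = config.resolve_separation(data.x)
    rows, ses, covs = [], [], []
    n_flagged = 0
    dropped = 0
    for i, child in enumerate(ss.spawn(D2)):
        rep_rng = np.random.default_rng(child)
        res = rao_wu_resample(data.design, rng=rep_rng, replicate_id=i)
        rep = data.with_weights(res.rescaled_weight)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_fixed_start(rep, chosen_fit.spec.knots, config)
        except (FitError, ValueError):
            dropped += 1
            continue
        if not fit.converged:
            dropped += 1
            continue
        kn = np.asarray(fit.spec.knots)
        if kn.size and (np.any(kn < fit.spec.lower + 2 * delta)
                        or np.any(kn > fit.spec.upper - 2 * delta)):
            n_flagged += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, cov, se, _ = observed_information(fit, rep)
        rows.append(piecewise_param_vector(fit))
        ses.append(se)
        if store_cov:
            covs.append(cov)
    if dropped > 0.1 * D2:
        warnings.warn(f"{dropped}/{D2} bootstrap replicates dropped "
                      "(non-convergence)", stacklevel=2)
    table = pd.DataFrame(rows, columns=names)
    se_table = pd.DataFrame(ses, columns=names)
    usable = len(table)
    flag_rate = n_flagged / usable if usable else float("nan")
    cov_arr = np.array(covs) if store_cov else None
    return table, se_table, dropped, flag_rate, cov_arr


def bootstrap_t_ci(estimates, point_se, replicates, replicate_se,
                   level: float = 0.95):
    """Equal-tail bootstrap-t interval per parameter.

    Replicates with non-positive or non-finite SE are dropped; fewer than 50
    usable replicates is an error (the tails cannot be located reliably).
    """
    est = np.asarray(estimates, float)
    se = np.asarray(point_se, float)
    reps = np.asarray(replicates, float)
    rse = np.asarray(replicate_se, float)
    d = est.size
    alpha = 1.0 - level
    lower = np.empty(d)
    upper = np.empty(d)
    for j in range(d):
        ok = np.isfinite(reps[:, j]) & np.isfinite(rse[:, j]) & (rse[:, j] > 0)
        if ok.sum() < 50:
            raise FitError(
                f"only {int(ok.sum())} usable replicates for parameter {j}; "
                "need at least 50 for bootstrap-t critical values")
        T = (reps[ok, j] - est[j]) / rse[ok, j]
        t_lo, t_hi = np.quantile(T, [alpha / 2.0, 1.0 - alpha / 2.0])
        lower[j] = est[j] - t_hi * se[j]
        upper[j] = est[j] - t_lo * se[j]
    return pd.DataFrame({"lower": lower, "upper": upper})


def bootstrap_inference(data: ModelData, chosen_fit: ModelFit, D2: int = 1000,
                        config: FitConfig | None = None, rng=None,
                        level: float = 0.95,
                        store_cov: bool = False) -> BootstrapInference:
    """Full design-based inference pipeline for a chosen-K fit."""
    config = config or FitConfig()
    names = piecewise_param_names(chosen_fit.K, data.p)
    est = piecewise_param_vector(chosen_fit)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, point_cov, point_se, _ = observed_information(chosen_fit, data)
    table, se_table, dropped, flag_rate, covs = psu_bootstrap_fit(
        data, chosen_fit, D2=D2, config=config, rng=rng, store_cov=store_cov)
    reps = table.to_numpy()
    boot_se = np.sqrt(np.sum((reps - reps.mean(axis=0)) ** 2, axis=0)
                      / (len(reps) - 1))
    ci = bootstrap_t_ci(est, point_se, reps, se_table.to_numpy(), level)
    ci.index = names
    return BootstrapInference(
        names=names, estimates=est, point_se=point_se, replicates=table,
        replicate_se=se_table, boot_se=boot_se, ci=ci, level=level, D2=D2,
        n_dropped=dropped, boundary_flag_rate=flag_rate,
        replicate_cov=covs, point_cov=point_cov if store_cov else None)


# ---------------------------------------------------------------------------
# odds ratios

def odds_ratio(pw: PiecewiseModel, x1: float, x2: float) -> float:
    """OR comparing predictor values x1 vs x2: exp of the log-odds difference.

    The covariate contributions cancel, so the ratio holds for any two
    otherwise-similar individuals.
    """
    h1 = piecewise_eval(pw, [x1])[0]
    h2 = piecewise_eval(pw, [x2])[0]
    return float(np.exp(h1 - h2))


def _log_or_grad(theta: np.ndarray, x: float, reference: float, K: int, p: int,
                 base_spec: SplineSpec, h_scale: float = 1e-6) -> np.ndarray:
    """Finite-difference gradient of log OR(x, reference) in the piecewise
    parameters (zero in the covariate block by construction)."""
    def log_or(t):
        pw, _ = _unpack(t, K, p, base_spec)
        return (piecewise_eval(pw, [x])[0] - piecewise_eval(pw, [reference])[0])
    g = np.zeros(theta.size)
    for i in range(2 * K + 2):  # a0, slopes, knots; betas cancel
        h = h_scale * max(1.0, abs(theta[i]))
        e = np.zeros(theta.size); e[i] = h
        g[i] = (log_or(theta + e) - log_or(theta - e)) / (2 * h)
    return g


def or_curve(pw: PiecewiseModel, reference: float, grid,
             inference: BootstrapInference | None = None,
             level: float = 0.95) -> pd.DataFrame:
    """OR at each grid point against a fixed reference value.

    The log-OR curve is piecewise linear with breakpoints at the knots and
    is exactly 1 at the reference.  With a :class:`BootstrapInference`
    carrying replicate covariances, pointwise bootstrap-t CIs on the log-OR
    are added (delta-method SEs per replicate).
    """
    grid = np.atleast_1d(np.asarray(grid, float))
    if grid.size == 0:
        raise ValueError("empty evaluation grid")
    href = piecewise_eval(pw, [reference])[0]
    log_or = piecewise_eval(pw, grid) - href
    out = pd.DataFrame({"x": grid, "log_or": log_or, "odds_ratio": np.exp(log_or)})
    if inference is None:
        return out
    if inference.replicate_cov is None or inference.point_cov is None:
        raise ValueError("inference must be built with store_cov=True for CIs")
    K = len(pw.slopes) - 1
    p = len(inference.names) - (2 * K + 2)
    reps = inference.replicates.to_numpy()
    est = inference.estimates
    alpha = 1.0 - level
    lo = np.empty(grid.size)
    hi = np.empty(grid.size)
    for g_idx, xg in enumerate(grid):
        def rep_log_or(t):
            pw_r, _ = _unpack(t, K, p, pw.spec)
            return (piecewise_eval(pw_r, [xg])[0]
                    - piecewise_eval(pw_r, [reference])[0])
        point = log_or[g_idx]
        grad0 = _log_or_grad(est, xg, reference, K, p, pw.spec)
        se0 = float(np.sqrt(max(grad0 @ inference.point_cov @ grad0, 1e-300)))
        Ts = []
        for r in range(reps.shape[0]):
            th = reps[r]
            gr = _log_or_grad(th, xg, reference, K, p, pw.spec)
            var = gr @ inference.replicate_cov[r] @ gr
            if not np.isfinite(var) or var <= 0:
                continue
            Ts.append((rep_log_or(th) - point) / np.sqrt(var))
        Ts = np.asarray(Ts)
        t_lo, t_hi = np.quantile(Ts, [alpha / 2.0, 1.0 - alpha / 2.0])
        lo[g_idx] = point - t_hi * se0
        hi[g_idx] = point - t_lo * se0
    out["log_or_lower"] = lo
    out["log_or_upper"] = hi
    out["or_lower"] = np.exp(lo)
    out["or_upper"] = np.exp(hi)
    return out
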