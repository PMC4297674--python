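"""Survey-weighted free-knot logistic regression.

The model for subject ``q`` is ``logit P(Y_q = 1) = Z_q beta + B_q b`` where
``Z`` holds a constant column plus ``p`` covariates and ``B`` is the retained
order-2 B-spline design of the continuous predictor with ``K`` free interior
knots.  The fit maximizes the sample-weighted pseudo-log-likelihood

    log L = sum_q w_q [ y_q eta_q - log(1 + exp(eta_q)) ],

with the weights entering raw (unnormalized) so that the likelihood is on
the scale the survey weights dictate.

Optimization strategy: for fixed knots the coefficient problem is an
ordinary (concave) weighted logistic regression, solved exactly by Newton
iterations; the knots are the only genuinely non-linear parameters and are
optimized by a quasi-Newton method with finite-difference gradients on the
profile likelihood.  Knot ordering and minimum-separation constraints are
enforced at every evaluated point through a monotone reparameterization of
the inter-knot gaps (softmax allocation of the slack beyond the mandatory
gaps), so the optimizer can never propose an invalid knot vector.  Starting
knot locations come from a combinatorial grid search over ``C`` candidate
positions spread across the predictor range.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit

from .basis import (
    PiecewiseModel,
    SeparationError,
    SplineSpec,
    bspline_basis,
    make_spline_spec,
    to_piecewise,
    truncated_power_basis,
)
from .survey import SurveyDesign

__all__ = [
    "ModelData",
    "ModelFit",
    "FitConfig",
    "FitError",
    "GridSearchError",
    "bernoulli_loglik",
    "weighted_loglik",
    "linear_logistic_start",
    "fit_fixed_start",
    "grid_search_fit",
    "candidate_start_knots",
]


class FitError(RuntimeError):
    """Model fitting failed."""


class GridSearchError(FitError):
    """No grid start converged; carries the best flagged fit found."""

    def __init__(self, message: str, best_fit: "ModelFit | None" = None):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass
class ModelData:
    """Subject-level data: binary outcome, continuous predictor, covariates.

    ``Z`` is the ``N x (p+1)`` covariate matrix with a leading constant
    column.  When no :class:`~freeknot.survey.SurveyDesign` is attached all
    weights are 1 and the likelihood is the ordinary Bernoulli one.
    """

    y: np.ndarray
    x: np.ndarray
    Z: np.ndarray
    design: SurveyDesign | None = None
    _weights_override: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        n = self.y.size
        if self.x.size != n or self.Z.shape[0] != n:
            raise ValueError("y, x and Z must have matching lengths")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("x must be finite")
        if not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("y must be strictly binary (0/1)")
        if self.design is not None and self.design.n != n:
            raise ValueError("survey design length mismatch")

    @classmethod
    def from_arrays(cls, y, x, covariates=None, design=None,
                    weights=None) -> "ModelData":
        y = np.asarray(y, dtype=float)
        n = y.size
        if covariates is None:
            Z = np.ones((n, 1))
        else:
            cov = np.atleast_2d(np.asarray(covariates, dtype=float))
            if cov.shape[0] != n:
                cov = cov.T
            Z = np.column_stack([np.ones(n), cov])
        data = cls(y=y, x=np.asarray(x, float), Z=Z, design=design)
        if weights is not None:
            data._weights_override = np.asarray(weights, dtype=float)
        return data

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        """Number of covariates excluding the intercept."""
        return self.Z.shape[1] - 1

    @property
    def weights(self) -> np.ndarray:
        if self._weights_override is not None:
            return self._weights_override
        if self.design is not None:
            return self.design.weight
        return np.ones(self.n)

    def with_outcomes(self, y) -> "ModelData":
        """Same predictors/design with replacement outcomes (bootstrap replicates)."""
        new = ModelData(y=np.asarray(y, float), x=self.x, Z=self.Z, design=self.design)
        new._weights_override = self._weights_override
        return new

    def with_weights(self, weights) -> "ModelData":
        """Same data with replacement weights (Rao-Wu replicates)."""
        new = ModelData(y=self.y, x=self.x, Z=self.Z, design=self.design)
        new._weights_override = np.asarray(weights, dtype=float)
        return new

    def with_normalized_weights(self) -> "ModelData":
        """Diagnostic mode: weights rescaled to sum to n.

        Point estimates are unchanged (the likelihood is scaled by a
        constant); the likelihood returns to the sample-size scale on which
        AIC/BIC penalties are meaningful.  Design-based inference should use
        the raw weights.
        """
        w = self.weights
        return self.with_weights(w * (self.n / float(w.sum())))

    def fingerprint(self) -> tuple:
        return (self.n, float(self.y.sum()), float(self.x.sum()),
                float(self.weights.sum()), self.Z.shape[1])


@dataclass
class FitConfig:
    """Tuning knobs for the free-knot optimizer.

    ``grid_points`` is the number ``C`` of candidate start locations spread
    evenly over the predictor range; a ``K``-knot search tries every size-K
    combination.  ``min_separation`` defaults to 1% of the predictor range.
    """

    grid_points: int = 6
    min_separation: float | None = None
    max_iterations: int = 500
    fd_rel_step: float = 1e-6
    gradient_tol: float = 1e-5
    inner_tol: float = 1e-10
    inner_max_iter: int = 60

    def resolve_separation(self, x: np.ndarray) -> float:
        if self.min_separation is not None:
            return self.min_separation
        return 0.01 * (float(np.max(x)) - float(np.min(x)))


@dataclass
class ModelFit:
    """A fitted free-knot logistic model.

    ``beta`` holds the intercept and covariate coefficients, ``spline_coefs``
    the retained B-spline coefficients ``b_1 ... b_{K+1}``, and ``spec`` the
    fitted knots.  ``neg_loglik`` is the minimized negative weighted
    log-likelihood.
    """

    spec: SplineSpec
    beta: np.ndarray
    spline_coefs: np.ndarray
    neg_loglik: float
    converged: bool
    n_obs: int
    data_fingerprint: tuple = ()
    n_starts: int = 1
    message: str = ""

    @property
    def K(self) -> int:
        return self.spec.K

    @property
    def p(self) -> int:
        return len(self.beta) - 1

    @property
    def n_params(self) -> int:
        """Free-parameter count ``p + 2K + 2`` (covariates + intercept +
        K knots + K+1 spline coefficients)."""
        return self.p + 2 * self.K + 2

    def linear_predictor(self, x, Z=None) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, float))
        s = bspline_basis(x, self.spec) @ self.spline_coefs
        if Z is None:
            return self.beta[0] + s
        return np.asarray(Z, float) @ self.beta + s

    def predict_proba(self, x, Z=None) -> np.ndarray:
        return expit(self.linear_predictor(x, Z))

    def to_piecewise(self) -> PiecewiseModel:
        """Reparameterize into intercept plus local slopes (covariates aside)."""
        return to_piecewise(self.spec, self.spline_coefs, intercept=float(self.beta[0]))

    def summary(self) -> dict:
        pw = self.to_piecewise()
        return {
            "K": self.K,
            "knots": list(self.spec.knots),
            "intercept": pw.intercept,
            "slopes": list(pw.slopes),
            "covariate_coefs": self.beta[1:].tolist(),
            "neg_loglik": self.neg_loglik,
            "n_params": self.n_params,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# likelihood

def bernoulli_loglik(eta, y, w) -> float:
    """Weighted Bernoulli log-likelihood, stabilized through log1p-exp."""
    eta = np.asarray(eta, float)
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def weighted_loglik(beta, spline_coefs, spec: SplineSpec, data: ModelData,
                    basis: str = "bspline") -> float:
    """Weighted log-likelihood at explicit parameters (Bernoulli pseudo-likelihood)."""
    beta = np.asarray(beta, float)
    if basis == "bspline":
        B = bspline_basis(data.x, spec)
    else:
        B = truncated_power_basis(data.x, spec)
    eta = data.Z @ beta + B @ np.asarray(spline_coefs, float)
    return bernoulli_loglik(eta, data.y, data.weights)


# ---------------------------------------------------------------------------
# inner (concave) coefficient solver

def _irls(X: np.ndarray, y: np.ndarray, w: np.ndarray, start=None,
          tol: float = 1e-10, max_iter: int = 60):
    """Newton/IRLS for weighted logistic regression.

    Returns ``(coef, neg_loglik, converged)``.  A small ridge keeps the
    Hessian solvable when a basis column is (nearly) collinear, e.g. when a
    knot drifts into a data-sparse segment.
    """
    n, d = X.shape
    coef = np.zeros(d) if start is None else np.array(start, float)
    sw = max(float(np.sum(w)), 1.0)
    nll = -bernoulli_loglik(X @ coef, y, w)
    converged = False
    for _ in range(max_iter):
        eta = X @ coef
        mu = expit(eta)
        grad = X.T @ (w * (y - mu))
        if np.max(np.abs(grad)) < 1e-9 * sw:
            converged = True
            break
        wt = w * mu * (1.0 - mu)
        H = X.T @ (wt[:, None] * X)
        ridge = 1e-10 * (np.trace(H) / d + 1.0)
        try:
            step = np.linalg.solve(H + ridge * np.eye(d), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving on the (convex) objective
        new_nll = None
        for _ in range(30):
            cand = coef + step
            cand_nll = -bernoulli_loglik(X @ cand, y, w)
            if cand_nll <= nll + 1e-12 * sw:
                new_nll = cand_nll
                coef = cand
                break
            step *= 0.5
        if new_nll is None:
            break
        if nll - new_nll < tol * max(1.0, abs(nll)):
            nll = new_nll
            converged = True
            break
        nll = new_nll
    if np.max(np.abs(coef)) > 1e4 or nll < 1e-8 * sw:
        converged = False  # (quasi-)separation: the MLE is diverging
    return coef, nll, converged


def linear_logistic_start(data: ModelData) -> np.ndarray:
    """Coefficient starts ``(beta_0, beta_1..beta_p, slope_x)`` from a
    one-slope weighted logistic regression.

    Falls back to the zero vector (with a warning) on separation or
    non-convergence, mirroring the known IRLS failure mode.
    """
    X = np.column_stack([data.Z, data.x])
    coef, _, ok = _irls(X, data.y, data.weights)
    if not ok:
        warnings.warn(
            "linear logistic start did not converge (possible separation); "
            "falling back to zero starting values", stacklevel=2)
        return np.zeros(X.shape[1])
    return coef


# ---------------------------------------------------------------------------
# knot-gap reparameterization (ordering/separation always satisfied)

def _free_length(spec_lower, spec_upper, K, delta) -> float:
    return (spec_upper - spec_lower) - (K + 1) * delta


def _u_to_knots(u: np.ndarray, lower: float, upper: float, delta: float) -> np.ndarray:
    K = u.size
    L = _free_length(lower, upper, K, delta)
    logits = np.concatenate([u, [0.0]])
    logits = logits - logits.max()
    s = np.exp(logits)
    s = L * s / s.sum()
    return lower + delta * np.arange(1, K + 1) + np.cumsum(s[:-1])


def _knots_to_u(knots: np.ndarray, lower: float, upper: float, delta: float) -> np.ndarray:
    seq = np.concatenate([[lower], knots, [upper]])
    gaps = np.diff(seq) - delta
    L = _free_length(lower, upper, knots.size, delta)
    gaps = np.maximum(gaps, 1e-10 * max(L, 1.0))
    logs = np.log(gaps)
    return logs[:-1] - logs[-1]


# ---------------------------------------------------------------------------
# fitting

def _coef_start(data: ModelData, spec: SplineSpec, lin_coef: np.ndarray) -> np.ndarray:
    """Map the linear-logistic start onto the (beta, b) coefficient space.

    Spline coefficients start on the fitted straight line (zero start for
    the deviation from linearity), covariate coefficients at their one-slope
    estimates.
    """
    slope = lin_coef[-1]
    beta = np.array(lin_coef[:-1], float)
    beta[0] = beta[0] + slope * spec.lower
    b = slope * (spec.knot_sequence[1:] - spec.lower)
    return np.concatenate([beta, b])


def fit_fixed_start(data: ModelData, start_knots, config: FitConfig | None = None,
                    lin_coef: np.ndarray | None = None,
                    bracket: tuple[float, float] | None = None) -> ModelFit:
    """Maximize the weighted likelihood over coefficients and knots from one
    knot starting vector.

    The coefficient subproblem is solved exactly (Newton) at every knot
    vector the outer quasi-Newton evaluates; finite-difference gradients
    drive the outer search; ordering/separation constraints hold by
    construction of the gap reparameterization.  ``K = 0`` reduces to a
    plain (weighted) logistic fit with no outer stage.
    """
    config = config or FitConfig()
    delta = config.resolve_separation(data.x)
    start_knots = np.sort(np.atleast_1d(np.asarray(start_knots, float))) \
        if np.size(start_knots) else np.empty(0)
    # validates bounds/ordering/separation of the start
    spec0 = make_spline_spec(data.x, start_knots, delta)
    K = spec0.K
    y, w = data.y, data.weights
    sw = max(float(w.sum()), 1.0)
    if lin_coef is None:
        lin_coef = linear_logistic_start(data)

    def solve_coefs(spec, start):
        X = np.column_stack([data.Z, bspline_basis(data.x, spec)])
        return _irls(X, y, w, start=start, tol=config.inner_tol,
                     max_iter=config.inner_max_iter)

    if K == 0:
        coef, nll, ok = solve_coefs(spec0, _coef_start(data, spec0, lin_coef))
        return ModelFit(spec0, coef[:data.p + 1], coef[data.p + 1:], nll, ok,
                        data.n, data.fingerprint())

    # hot path: profile objective works on raw knot arrays, writing the
    # basis block of a preallocated design matrix in place
    n, pz = data.n, data.Z.shape[1]
    X = np.empty((n, pz + K + 1))
    X[:, :pz] = data.Z
    rows = np.arange(n)
    carry = {"coef": _coef_start(data, spec0, lin_coef)}
    a, b = spec0.lower, spec0.upper

    def nll_at_knots(knots):
        seq = np.empty(K + 2)
        seq[0], seq[-1] = a, b
        seq[1:-1] = knots
        idx = np.clip(np.searchsorted(seq, data.x, side="right") - 1, 0, K)
        t = (data.x - seq[idx]) / (seq[idx + 1] - seq[idx])
        Bblock = X[:, pz:]
        Bblock[:] = 0.0
        mask = idx > 0
        Bblock[rows[mask], idx[mask] - 1] = 1.0 - t[mask]
        Bblock[rows, idx] = t
        coef, nll, _ = _irls(X, y, w, start=carry["coef"],
                             tol=config.inner_tol,
                             max_iter=config.inner_max_iter)
        carry["coef"] = coef
        return nll / sw

    if K == 1 and bracket is not None:
        # one free knot restricted to a window: bounded 1-D minimization of
        # the profile likelihood (no gradient needed)
        lo = max(a + delta, bracket[0])
        hi = min(b - delta, bracket[1])
        res = minimize_scalar(lambda z: nll_at_knots(np.array([z])),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-3 * (b - a)})
        final_knots = np.array([res.x])
        converged_outer = bool(res.success)
    else:
        u0 = _knots_to_u(start_knots, spec0.lower, spec0.upper, delta)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = minimize(lambda u: nll_at_knots(_u_to_knots(u, a, b, delta)),
                           u0, method="BFGS",
                           options={"gtol": config.gradient_tol,
                                    "maxiter": config.max_iterations,
                                    "xrtol": 1e-7,
                                    "finite_diff_rel_step": config.fd_rel_step})
        final_knots = _u_to_knots(res.x, a, b, delta)
        # BFGS often exits with "precision loss" at a usable optimum; accept
        # when the scaled gradient is negligible next to O(1) curvature
        converged_outer = bool(res.success) or float(np.max(np.abs(res.jac))) < 2e-3
    spec = spec0.with_knots(final_knots)
    coef, nll, inner_ok = solve_coefs(spec, carry["coef"])
    converged = converged_outer and inner_ok
    return ModelFit(spec, coef[:data.p + 1], coef[data.p + 1:], nll, converged,
                    data.n, data.fingerprint(), message=str(res.message))


def candidate_start_knots(data: ModelData, K: int, config: FitConfig | None = None):
    """Size-``K`` combinations of the ``C`` grid candidates, skipping starts
    whose inter-knot segments would hold no observations."""
    config = config or FitConfig()
    delta = config.resolve_separation(data.x)
    a, b = float(data.x.min()), float(data.x.max())
    C = config.grid_points
    if C < max(K, 1):
        raise ValueError(f"grid_points={C} too small for a {K}-knot search")
    if K == 0:
        return [()]
    grid = np.linspace(a + delta, b - delta, C)
    out = []
    for combo in itertools.combinations(grid, K):
        knots = np.asarray(combo)
        if np.any(np.diff(knots) < delta):
            continue
        seq = np.concatenate([[a], knots, [b]])
        counts, _ = np.histogram(data.x, bins=seq)
        if np.any(counts == 0):
            continue
        out.append(tuple(knots))
    return out


def _simplex_polish(data: ModelData, fit: ModelFit, config: FitConfig,
                    lin_coef: np.ndarray) -> ModelFit:
    """Refine a fitted knot vector with a short Nelder-Mead pass.

    The profile likelihood has derivative kinks where a knot crosses an
    observation, which can strand a gradient-based search in a shallow
    secondary basin; a simplex probe from the incumbent escapes those at
    modest cost.  The refined fit is kept only when it improves the
    likelihood.
    """
    K = fit.K
    if K == 0:
        return fit
    delta = config.resolve_separation(data.x)
    a, b = fit.spec.lower, fit.spec.upper
    y, w = data.y, data.weights
    sw = max(float(w.sum()), 1.0)
    n, pz = data.n, data.Z.shape[1]
    X = np.empty((n, pz + K + 1))
    X[:, :pz] = data.Z
    rows = np.arange(n)
    carry = {"coef": np.concatenate([fit.beta, fit.spline_coefs])}

    def objective(raw):
        knots = np.sort(raw)
        if (knots[0] < a + delta or knots[-1] > b - delta
                or np.any(np.diff(knots) < delta)):
            return 1e10
        seq = np.empty(K + 2)
        seq[0], seq[-1] = a, b
        seq[1:-1] = knots
        idx = np.clip(np.searchsorted(seq, data.x, side="right") - 1, 0, K)
        t = (data.x - seq[idx]) / (seq[idx + 1] - seq[idx])
        Bblock = X[:, pz:]
        Bblock[:] = 0.0
        mask = idx > 0
        Bblock[rows[mask], idx[mask] - 1] = 1.0 - t[mask]
        Bblock[rows, idx] = t
        coef, nll, _ = _irls(X, y, w, start=carry["coef"],
                             tol=config.inner_tol,
                             max_iter=config.inner_max_iter)
        carry["coef"] = coef
        return nll / sw

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = minimize(objective, np.asarray(fit.spec.knots),
                       method="Nelder-Mead",
                       options={"xatol": 1e-5 * (b - a), "fatol": 1e-11,
                                "maxfev": 150 * K})
    if not np.isfinite(res.fun) or res.fun * sw >= fit.neg_loglik - 1e-9:
        return fit
    spec = fit.spec.with_knots(np.sort(res.x))
    Xf = np.column_stack([data.Z, bspline_basis(data.x, spec)])
    coef, nll, ok = _irls(Xf, y, w, start=carry["coef"],
                          tol=config.inner_tol, max_iter=config.inner_max_iter)
    if nll >= fit.neg_loglik:
        return fit
    return ModelFit(spec, coef[:data.p + 1], coef[data.p + 1:], nll,
                    fit.converged and ok, data.n, data.fingerprint(),
                    n_starts=fit.n_starts, message=fit.message)


def grid_search_fit(data: ModelData, K: int, config: FitConfig | None = None) -> ModelFit:
    """Best converged fit over all grid-searched knot starting combinations.

    Ties in achieved log-likelihood (within 1e-9) break toward the
    lexicographically smallest knot vector.  If no start converges a
    :class:`GridSearchError` is raised carrying the best flagged fit.
    """
    config = config or FitConfig()
    starts = candidate_start_knots(data, K, config)
    if not starts:
        raise GridSearchError(f"no admissible {K}-knot starting combinations")
    lin_coef = linear_logistic_start(data)
    delta = config.resolve_separation(data.x)
    a, b = float(data.x.min()), float(data.x.max())
    spacing = (b - a - 2 * delta) / max(config.grid_points - 1, 1)
    fits = []
    for s in starts:
        try:
            # a one-knot search is 1-D: bounded minimization within an
            # overlapping window around each grid candidate
            br = (s[0] - spacing, s[0] + spacing) if K == 1 else None
            fits.append(fit_fixed_start(data, s, config, lin_coef=lin_coef,
                                        bracket=br))
        except (SeparationError, FitError):
            continue
    if not fits:
        raise GridSearchError(f"all {len(starts)} starts failed for K={K}")
    converged = [f for f in fits if f.converged]
    pool = converged if converged else fits
    best = min(pool, key=lambda f: (round(f.neg_loglik, 9), f.spec.knots))
    best.n_starts = len(starts)
    if not converged:
        raise GridSearchError(
            f"no converged fit among {len(starts)} starts for K={K}", best_fit=best)
    return _simplex_polish(data, best, config, lin_coef)
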