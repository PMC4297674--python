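"""Plasmode-style synthetic data: BMI-like predictor, true piecewise
log-odds model, prevalence-calibrated intercept, and multistage designs.

The default true model is U-shaped on BMI in [17, 45]: log-odds falling at
slope -0.4 below BMI 25, flat between 25 and 32, rising at slope 0.2 above
32 — the classic pattern of mortality risk elevated at both low and high
BMI.  The intercept is recalibrated per dataset so the mean event
probability hits a target prevalence ``p0``.

A true plasmode would condition on real survey BMI records; the default
predictor here is a documented synthetic stand-in (truncated log-normal),
and ``ModelData`` construction accepts any user-supplied predictor vector
for faithful plasmode use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .basis import PiecewiseModel, SplineSpec, piecewise_eval
from .fitting import ModelData
from .survey import SurveyDesign

__all__ = [
    "TrueModel",
    "SimConfig",
    "synth_bmi",
    "true_eta",
    "calibrate_intercept",
    "simulate_outcomes",
    "synth_design",
    "simulate_dataset",
]


@dataclass
class TrueModel:
    """The generating piecewise linear log-odds model."""

    knots: tuple[float, ...] = (25.0, 32.0)
    slopes: tuple[float, ...] = (-0.4, 0.0, 0.2)
    intercept: float = 0.0
    domain: tuple[float, float] = (17.0, 45.0)

    def __post_init__(self) -> None:
        if len(self.slopes) != len(self.knots) + 1:
            raise ValueError("need one slope per inter-knot segment "
                             f"({len(self.knots) + 1}), got {len(self.slopes)}")
        lo, hi = self.domain
        if self.knots and not all(lo < z < hi for z in self.knots):
            raise ValueError("knots must lie strictly inside the domain")

    @property
    def spec(self) -> SplineSpec:
        return SplineSpec(self.domain[0], self.domain[1], tuple(self.knots), 0.0)

    def to_piecewise(self) -> PiecewiseModel:
        return PiecewiseModel(self.spec, self.intercept, tuple(self.slopes))

    def with_intercept(self, a0: float) -> "TrueModel":
        return TrueModel(self.knots, self.slopes, float(a0), self.domain)


@dataclass
class SimConfig:
    """One simulation condition: sample size, prevalence, design, replicates."""

    n: int = 5000
    p0: float = 0.33
    weighted: bool = False
    replicates: int = 100
    bmi_median: float = 25.5
    bmi_log_sd: float = 0.18
    H: int = 49
    n_h: int = 2
    weight_cv: float = 1.0
    mean_weight: float = 1e4
    weight_predictor_corr: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must be in (0, 1)")
        if self.n < 50:
            raise ValueError("n must be at least 50")


def synth_bmi(n: int, rng: np.random.Generator | int | None = None,
              median: float = 25.5, log_sd: float = 0.18,
              bounds: tuple[float, float] = (17.0, 45.0)) -> np.ndarray:
    """Right-skewed BMI-like draws: log-normal truncated to ``bounds``.

    The defaults (median 25.5, log-SD 0.18) give an adult-like distribution
    with most mass between 20 and 33 and a long right shoulder.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    lo, hi = bounds
    mu = np.log(median)
    out = np.empty(0)
    for _ in range(200):
        draw = rng.lognormal(mu, log_sd, size=2 * (n - out.size) + 16)
        keep = draw[(draw >= lo) & (draw <= hi)]
        if keep.size == 0 and out.size == 0:
            raise ValueError("truncation interval carries no probability mass")
        out = np.concatenate([out, keep])
        if out.size >= n:
            return out[:n]
    raise ValueError("truncation interval carries almost no probability mass")


def true_eta(x, model: TrueModel) -> np.ndarray:
    """True log-odds at ``x`` (piecewise linear evaluation)."""
    return piecewise_eval(model.to_piecewise(), x)


def calibrate_intercept(x, model: TrueModel, p0: float) -> float:
    """Solve ``mean(expit(a0 + s(x))) = p0`` for the intercept ``a0``.

    The mean event probability is strictly increasing in ``a0``, so the
    root is unique; solved by bracketed root-finding to 1e-10.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    x = np.asarray(x, float)
    s = true_eta(x, model.with_intercept(0.0))

    def gap(a0):
        return float(np.mean(expit(a0 + s))) - p0

    lo, hi = -40.0, 40.0
    return float(brentq(gap, lo, hi, xtol=1e-10))


def simulate_outcomes(x, model: TrueModel,
                      rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Independent Bernoulli outcomes at the true-model event probabilities."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pi = expit(true_eta(x, model))
    return (rng.random(np.size(x)) < pi).astype(float)


def synth_design(n: int, H: int = 49, n_h: int = 2,
                 rng: np.random.Generator | int | None = None,
                 weight_cv: float = 1.0, mean_weight: float = 1e4,
                 weight_predictor_corr: float = 0.0,
                 x: np.ndarray | None = None) -> SurveyDesign:
    """Synthetic multistage design: H strata x n_h PSUs, log-normal weights.

    Subjects are split into ``H * n_h`` near-equal clusters.  Weights are
    log-normal with coefficient of variation ``weight_cv`` and mean
    ``mean_weight`` (the population-per-subject scale of national surveys);
    ``weight_cv = 0`` gives equal weights.  ``weight_predictor_corr``
    optionally correlates log-weight with the standardized predictor to
    mimic oversampling of a tail.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_clusters = H * n_h
    if n_clusters > n:
        raise ValueError(f"cannot place {n} subjects into {n_clusters} non-empty PSUs")
    cluster = np.arange(n) % n_clusters  # sizes near-equal by construction
    rng.shuffle(cluster)
    stratum = cluster // n_h
    psu = cluster % n_h
    if weight_cv <= 0:
        weight = np.full(n, mean_weight)
    else:
        sigma2 = np.log1p(weight_cv ** 2)
        sigma = np.sqrt(sigma2)
        z = rng.standard_normal(n)
        if weight_predictor_corr != 0.0:
            if x is None:
                raise ValueError("weight_predictor_corr requires the predictor x")
            rho = float(np.clip(weight_predictor_corr, -1.0, 1.0))
            zx = (np.asarray(x, float) - np.mean(x)) / np.std(x)
            z = rho * zx + np.sqrt(1.0 - rho ** 2) * z
        mu = np.log(mean_weight) - sigma2 / 2.0
        weight = np.exp(mu + sigma * z)
    return SurveyDesign(stratum=stratum, psu=psu, weight=weight)


def simulate_dataset(config: SimConfig, rng: np.random.Generator | int | None = None,
                     model: TrueModel | None = None,
                     x: np.ndarray | None = None):
    """One replicate dataset under a condition.

    Returns ``(ModelData, calibrated TrueModel)``.  The intercept is
    recalibrated for every dataset since it must condition on the realized
    predictor draw.  A user-supplied ``x`` (e.g. real survey BMI records)
    switches the generator into true plasmode mode.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    model = model or TrueModel()
    if x is None:
        lo, hi = model.domain
        x = synth_bmi(config.n, rng, median=config.bmi_median,
                      log_sd=config.bmi_log_sd, bounds=(lo, hi))
    else:
        x = np.asarray(x, float)
    a0 = calibrate_intercept(x, model, config.p0)
    model = model.with_intercept(a0)
    y = simulate_outcomes(x, model, rng)
    design = None
    if config.weighted:
        design = synth_design(len(x), H=config.H, n_h=config.n_h, rng=rng,
                              weight_cv=config.weight_cv,
                              mean_weight=config.mean_weight,
                              weight_predictor_corr=config.weight_predictor_corr,
                              x=x)
    data = ModelData.from_arrays(y=y, x=x, design=design)
    return data, model
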