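"""Order-2 (piecewise linear) spline bases and the piecewise-slope reparameterization.

A piecewise linear spline on ``[a, b]`` with ``K`` interior knots
``zeta_1 < ... < zeta_K`` can be written in three equivalent ways:

* as an order-2 B-spline expansion built from the de Boor recurrence with
  doubled boundary knots (numerically stable; used for optimization),
* as a truncated power expansion ``beta_1 x + sum_i b_i (x - zeta_i)_+``
  (algebraically transparent; kept for cross-checking), or
* directly in terms of an intercept and one local slope per inter-knot
  segment (the human-readable form reported to users).

This module constructs the first two as plain design matrices and converts
fitted coefficients into the third.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SplineSpec",
    "PiecewiseModel",
    "DomainError",
    "SeparationError",
    "make_spline_spec",
    "bspline_basis",
    "truncated_power_basis",
    "spline_part",
    "to_piecewise",
    "piecewise_eval",
]


class DomainError(ValueError):
    """A value (knot or evaluation point) falls outside the spline domain."""


class SeparationError(ValueError):
    """Adjacent knots (including boundaries) are closer than the minimum gap."""


@dataclass(frozen=True)
class SplineSpec:
    """Boundary interval plus ordered interior knots of an order-2 spline.

    Parameters
    ----------
    lower, upper
        Fixed boundary knots ``a = min(x)`` and ``b = max(x)``; never estimated.
    knots
        Ordered interior knots ``zeta_1 < ... < zeta_K``; ``K = 0`` gives a
        single linear segment.
    min_separation
        Minimal distance ``delta > 0`` enforced between any two knots,
        boundaries included.
    """

    lower: float
    upper: float
    knots: tuple[float, ...] = ()
    min_separation: float = field(default=0.0)
    order: int = 2

    def __post_init__(self) -> None:
        if not np.isfinite(self.lower) or not np.isfinite(self.upper):
            raise DomainError("spline bounds must be finite")
        if self.upper <= self.lower:
            raise DomainError("upper bound must exceed lower bound")
        if self.order != 2:
            raise ValueError("only order-2 (piecewise linear) splines are supported")
        kn = np.asarray(self.knots, dtype=float)
        if kn.size and (kn.min() <= self.lower or kn.max() >= self.upper):
            raise DomainError(
                f"interior knots {self.knots} must lie strictly inside "
                f"({self.lower}, {self.upper})"
            )
        seq = np.concatenate([[self.lower], kn, [self.upper]])
        gaps = np.diff(seq)
        if self.min_separation > 0 and np.any(gaps < self.min_separation - 1e-12):
            raise SeparationError(
                f"adjacent knots closer than min_separation={self.min_separation}: "
                f"gaps {gaps.tolist()}"
            )
        if np.any(gaps <= 0):
            raise SeparationError("knots must be strictly increasing")

    @property
    def K(self) -> int:
        """Number of interior knots."""
        return len(self.knots)

    @property
    def knot_sequence(self) -> np.ndarray:
        """Boundary and interior knots: ``[a, zeta_1, ..., zeta_K, b]``."""
        return np.concatenate([[self.lower], np.asarray(self.knots, float), [self.upper]])

    def with_knots(self, knots) -> "SplineSpec":
        return SplineSpec(self.lower, self.upper, tuple(float(z) for z in knots),
                          self.min_separation)


def make_spline_spec(x, interior_knots=(), min_separation: float | None = None) -> SplineSpec:
    """Build a validated :class:`SplineSpec` with bounds taken from the data.

    ``min_separation`` defaults to 1% of the data range when not given.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise DomainError("x must be non-empty and finite")
    a, b = float(x.min()), float(x.max())
    if min_separation is None:
        min_separation = 0.01 * (b - a)
    knots = tuple(sorted(float(z) for z in np.atleast_1d(np.asarray(interior_knots, float))
                         )) if np.size(interior_knots) else ()
    return SplineSpec(a, b, knots, float(min_separation))


def _check_domain(x: np.ndarray, spec: SplineSpec) -> None:
    if x.size and (x.min() < spec.lower - 1e-12 or x.max() > spec.upper + 1e-12):
        raise DomainError(
            f"values outside spline domain [{spec.lower}, {spec.upper}]"
        )


def _interval_index(x: np.ndarray, seq: np.ndarray) -> np.ndarray:
    # half-open intervals [zeta_i, zeta_{i+1}); x == b is closed into the last
    idx = np.searchsorted(seq, x, side="right") - 1
    return np.clip(idx, 0, len(seq) - 2)


def bspline_basis(x, spec: SplineSpec, drop_first: bool = True) -> np.ndarray:
    """Order-2 B-spline design matrix with doubled boundary knots.

    The full basis has ``K + 2`` hat-function columns (one per knot including
    the boundaries) which sum to one at every ``x``.  The first column — the
    only one that is 1 at the left boundary — is dropped by default so a
    model keeps its own free intercept, leaving the ``K + 1`` columns that
    carry coefficients ``b_1 ... b_{K+1}``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    _check_domain(x, spec)
    seq = spec.knot_sequence
    idx = _interval_index(x, seq)
    left, right = seq[idx], seq[idx + 1]
    t = (x - left) / (right - left)
    B = np.zeros((x.size, len(seq)))
    rows = np.arange(x.size)
    B[rows, idx] = 1.0 - t
    B[rows, idx + 1] = t
    return B[:, 1:] if drop_first else B


def truncated_power_basis(x, spec: SplineSpec) -> np.ndarray:
    """Columns ``[x, (x - zeta_1)_+, ..., (x - zeta_K)_+]``."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    _check_domain(x, spec)
    cols = [x] + [np.maximum(x - z, 0.0) for z in spec.knots]
    return np.column_stack(cols)


def spline_part(x, spec: SplineSpec, spline_coefs, basis: str = "bspline") -> np.ndarray:
    """Evaluate the spline contribution ``s(x)`` for fitted coefficients.

    For the B-spline parameterization the coefficients are the retained
    (left-boundary-dropped) columns, so ``s(a) = 0``; for the truncated-power
    parameterization they are ``(a_1, b_1, ..., b_K)``.
    """
    coefs = np.asarray(spline_coefs, dtype=float)
    if basis == "bspline":
        M = bspline_basis(x, spec)
    elif basis == "truncated":
        M = truncated_power_basis(x, spec)
    else:  # pragma: no cover - guarded API
        raise ValueError(f"unknown basis {basis!r}")
    if M.shape[1] != coefs.size:
        raise ValueError(
            f"expected {M.shape[1]} spline coefficients, got {coefs.size}"
        )
    return M @ coefs


@dataclass(frozen=True)
class PiecewiseModel:
    """Piecewise linear log-odds: intercept ``a_0`` and one slope per segment.

    ``slopes[l]`` is the local slope on ``[zeta_l, zeta_{l+1})`` reading the
    knot sequence left to right, so there are ``K + 1`` slopes.
    """

    spec: SplineSpec
    intercept: float
    slopes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.slopes) != self.spec.K + 1:
            raise ValueError(
                f"need {self.spec.K + 1} slopes for K={self.spec.K}, "
                f"got {len(self.slopes)}"
            )

    @property
    def knot_values(self) -> np.ndarray:
        """Function values at ``[a, zeta_1, ..., zeta_K, b]`` (continuity anchors)."""
        seq = self.spec.knot_sequence
        vals = np.empty_like(seq)
        vals[0] = self.intercept + self.slopes[0] * seq[0]
        vals[1:] = vals[0] + np.cumsum(np.asarray(self.slopes) * np.diff(seq))
        return vals


def to_piecewise(spec: SplineSpec, spline_coefs, intercept: float = 0.0,
                 basis: str = "bspline") -> PiecewiseModel:
    """Convert fitted spline coefficients to intercept-plus-local-slopes form.

    Slopes are extracted by evaluating the fitted spline part at consecutive
    knots and differencing — exact for piecewise linear functions and
    agnostic to the basis used for fitting.  For truncated-power input this
    reproduces the cumulative-sum identity ``a_l = a_1 + sum_{i<l} b_i``.
    """
    seq = spec.knot_sequence
    g = intercept + spline_part(seq, spec, spline_coefs, basis=basis)
    slopes = np.diff(g) / np.diff(seq)
    a0 = g[0] - slopes[0] * seq[0]
    return PiecewiseModel(spec, float(a0), tuple(float(s) for s in slopes))


def piecewise_eval(pw: PiecewiseModel, x) -> np.ndarray:
    """Evaluate the continuous piecewise linear function at ``x``.

    Interval membership follows the half-open ``[zeta_i, zeta_{i+1})``
    convention with the upper boundary closed into the last interval; for a
    continuous function the convention only matters for the domain check.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    _check_domain(x, pw.spec)
    return np.interp(x, pw.spec.knot_sequence, pw.knot_values)
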