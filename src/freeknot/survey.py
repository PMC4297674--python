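"""Complex multistage survey designs and the Rao–Wu PSU bootstrap.

A design is the usual public-use triple per subject: stratum id, primary
sampling unit (PSU) id nested within stratum, and a positive sampling
weight.  Resampling draws ``d_h`` PSUs with replacement within each stratum
``h`` and rescales every subject's weight by

    w* = w [1 - sqrt(d_h/(n_h-1))] + w sqrt(d_h/(n_h-1)) (n_h/d_h) r_hi,

where ``n_h`` is the number of PSUs in the stratum and ``r_hi`` counts how
often PSU ``i`` was drawn.  With the default ``d_h = n_h - 1`` the first
term vanishes; in the common two-PSU-per-stratum design one PSU's subjects
double their weight and the other PSU's subjects get weight zero.  The
rescaling keeps weighted estimators unbiased: ``E[w*] = w``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurveyDesign",
    "ResampledDesign",
    "DesignError",
    "validate_design",
    "rao_wu_resample",
    "rescale_weights",
]


class DesignError(ValueError):
    """Invalid survey design (bad weights, missing ids, too few PSUs)."""


@dataclass(frozen=True)
class SurveyDesign:
    """Per-subject stratum / PSU / weight triple.

    PSU ids need only be unique within their stratum; nesting is enforced by
    always pairing ``(stratum, psu)``.
    """

    stratum: np.ndarray
    psu: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.weight)
        if not (len(self.stratum) == len(self.psu) == n):
            raise DesignError("stratum, psu and weight must have equal length")
        w = np.asarray(self.weight, dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise DesignError("all sampling weights must be finite and > 0")
        object.__setattr__(self, "weight", w)

    @property
    def n(self) -> int:
        return len(self.weight)

    @property
    def strata(self) -> np.ndarray:
        return np.unique(np.asarray(self.stratum))

    @property
    def H(self) -> int:
        """Number of strata."""
        return len(self.strata)

    def psu_counts(self) -> dict:
        """Number of distinct PSUs per stratum."""
        s = np.asarray(self.stratum)
        p = np.asarray(self.psu)
        return {h: len(np.unique(p[s == h])) for h in self.strata}

    def resamplable(self) -> bool:
        return all(n_h >= 2 for n_h in self.psu_counts().values())


@dataclass(frozen=True)
class ResampledDesign:
    """One Rao–Wu bootstrap replicate: rescaled weights on a stable row index.

    Subjects belonging to PSUs not drawn in this replicate keep their row but
    carry weight 0, so replicate datasets align with the original rows.
    """

    indices: np.ndarray
    rescaled_weight: np.ndarray
    replicate_id: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.rescaled_weight) < 0):
            raise DesignError("rescaled weights must be >= 0")


def validate_design(table: pd.DataFrame, stratum: str = "stratum",
                    psu: str = "psu", weight: str = "weight",
                    require_resamplable: bool = False) -> SurveyDesign:
    """Validate design columns of a subject-level table.

    Strata holding a single PSU are flagged with a warning; they are fatal
    only when ``require_resamplable`` is set (PSU resampling needs at least
    two PSUs everywhere).
    """
    for col in (stratum, psu, weight):
        if col not in table.columns:
            raise DesignError(f"missing design column {col!r}")
        if table[col].isna().any():
            raise DesignError(f"missing values in design column {col!r}")
    design = SurveyDesign(
        stratum=table[stratum].to_numpy(),
        psu=table[psu].to_numpy(),
        weight=table[weight].to_numpy(dtype=float),
    )
    singles = [h for h, n_h in design.psu_counts().items() if n_h < 2]
    if singles:
        msg = f"strata with a single PSU: {singles} (cannot be resampled)"
        if require_resamplable:
            raise DesignError(msg)
        warnings.warn(msg, stacklevel=2)
    return design


def rescale_weights(weight: np.ndarray, n_h: int, d_h: int,
                    r: np.ndarray) -> np.ndarray:
    """Apply the Rao–Wu rescaling within one stratum.

    ``r`` gives the draw count per subject (the ``r_hi`` of the subject's
    own PSU, broadcast to subjects).
    """
    if n_h < 2:
        raise DesignError("rescaling requires n_h >= 2")
    lam = np.sqrt(d_h / (n_h - 1))
    return weight * (1.0 - lam) + weight * lam * (n_h / d_h) * r


def rao_wu_resample(design: SurveyDesign, d_h: dict | int | None = None,
                    rng: np.random.Generator | int | None = None,
                    replicate_id: int = 0) -> ResampledDesign:
    """Draw one with-replacement PSU bootstrap replicate with rescaled weights.

    Parameters
    ----------
    d_h
        Number of PSUs to draw per stratum: an int applied to every stratum,
        a ``{stratum: d_h}`` mapping, or None for the default ``n_h - 1``.
    """
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = rng
        rng = np.random.default_rng(rng)
    s = np.asarray(design.stratum)
    p = np.asarray(design.psu)
    w_star = np.zeros(design.n)
    for h in design.strata:
        mask = s == h
        psus, inv = np.unique(p[mask], return_inverse=True)
        n_h = len(psus)
        if n_h < 2:
            raise DesignError(f"stratum {h!r} has {n_h} PSU; resampling needs >= 2")
        if d_h is None:
            d = n_h - 1
        elif isinstance(d_h, dict):
            d = int(d_h[h])
        else:
            d = int(d_h)
        if d < 1:
            raise DesignError(f"d_h must be >= 1 in stratum {h!r}")
        draws = rng.integers(0, n_h, size=d)
        r = np.bincount(draws, minlength=n_h).astype(float)
        w_star[mask] = rescale_weights(design.weight[mask], n_h, d, r[inv])
    return ResampledDesign(
        indices=np.arange(design.n),
        rescaled_weight=w_star,
        replicate_id=replicate_id,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
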