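"""Delimited-text reading with user-named column mapping."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import ModelData
from .survey import validate_design

__all__ = ["read_model_data"]


def read_model_data(path, outcome: str, predictor: str, covariates=(),
                    stratum: str | None = None, psu: str | None = None,
                    weight: str | None = None, sep: str = ",") -> ModelData:
    """Read a subject-level delimited file into :class:`ModelData`.

    Survey-design columns are optional but must be given together; without
    them all weights are 1 (SRS analysis).
    """
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in (outcome, predictor, *covariates) if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns {missing} in {path}")
    design = None
    design_cols = (stratum, psu, weight)
    if any(design_cols):
        if not all(design_cols):
            raise ValueError("stratum, psu and weight must be supplied together")
        design = validate_design(table, stratum=stratum, psu=psu, weight=weight)
    cov = table[list(covariates)].to_numpy(float) if covariates else None
    return ModelData.from_arrays(
        y=table[outcome].to_numpy(float),
        x=table[predictor].to_numpy(float),
        covariates=cov,
        design=design,
    )
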