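"""Multinutrient cycling index (MNC).

The MNC is the per-sample mean of z-scored soil nutrient-pool variables
(averaging multifunctionality index). Standardization is performed within
a stated cohort — by default all samples of one depth layer — so the index
has mean 0 over that cohort and treatment contrasts are within-layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .synthetic_data import NUTRIENT_VARIABLES

logger = logging.getLogger(__name__)


@dataclass
class MNCResult:
    mnc: pd.Series
    variables_used: tuple[str, ...]
    z_table: pd.DataFrame


def mnc_index(
    soil: pd.DataFrame,
    variables: Sequence[str] | None = None,
    cohort: Sequence[str] | None = None,
) -> MNCResult:
    """Mean of within-cohort z-scores of the selected nutrient variables.

    ``soil`` is samples x variables; ``cohort`` (default: all rows) names
    the samples used both for standardization and for the returned index.
    Zero-variance variables are dropped with a warning; if none remain a
    ValueError is raised.
    """
    variables = tuple(variables) if variables is not None else NUTRIENT_VARIABLES
    missing = [v for v in variables if v not in soil.columns]
    if missing:
        raise ValueError(f"soil table lacks requested variables: {missing}")
    rows = soil.index if cohort is None else pd.Index(cohort)
    if len(rows) < 2:
        raise ValueError("cohort must contain at least 2 samples")
    sub = soil.loc[rows, list(variables)].astype(float)

    sd = sub.std(ddof=1)
    dropped = [v for v in variables if sd[v] == 0 or pd.isna(sd[v])]
    if dropped:
        logger.warning("dropping zero-variance variables from MNC: %s", dropped)
    used = tuple(v for v in variables if v not in dropped)
    if not used:
        raise ValueError("no usable variables: all have zero variance in the cohort")
    z = (sub[list(used)] - sub[list(used)].mean()) / sd[list(used)]
    return MNCResult(mnc=z.mean(axis=1), variables_used=used, z_table=z)
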