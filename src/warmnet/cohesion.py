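"""Community cohesion and the |negative|:positive cohesion stability ratio.

Connectedness of a taxon is the mean of its null-corrected positive (resp.
negative) correlations with all other taxa; per-sample cohesion weights
those connectedness values by relative abundance. The null model is the
"taxa shuffle": each partner column is permuted independently across
samples, and the mean correlation over permutations is subtracted from the
observed one, removing correlation expected from abundance distributions
alone. NPC = |negative cohesion| / positive cohesion is the per-sample
stability proxy (higher = more stable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class Connectedness:
    """Per-taxon mean positive / negative null-corrected correlation."""

    c_pos: pd.Series  # in [0, 1]
    c_neg: pd.Series  # in [-1, 0]


@dataclass
class CohesionResult:
    """Per-sample abundance-weighted cohesion and the NPC stability ratio."""

    c_pos: pd.Series
    c_neg: pd.Series
    npc: pd.Series  # NaN where positive cohesion is 0 (flagged undefined)


def _standardized_columns(values: np.ndarray, method: str) -> np.ndarray:
    """Columns standardized to mean 0, norm 1; constant columns -> NaN."""
    if method == "spearman":
        values = stats.rankdata(values, axis=0)
    centered = values - values.mean(axis=0, keepdims=True)
    norm = np.linalg.norm(centered, axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = centered / norm
    z[:, norm[0] == 0] = np.nan
    return z


def null_corrected_correlations(
    abundance: pd.DataFrame,
    n_iter: int = 200,
    seed: int | None = None,
    method: str = "spearman",
) -> pd.DataFrame:
    """Observed minus null-mean correlation for every ordered taxon pair.

    ``abundance`` is samples x taxa. For the ordered pair (j, k) the null
    is the mean over ``n_iter`` iterations of the correlation between
    column j and an independent permutation of column k, so the returned
    matrix is not symmetric. ``n_iter=0`` returns the observed correlations
    (degenerate mode). Constant columns are recorded as missing (NaN).
    Deterministic given ``seed``.
    """
    if abundance.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    rng = np.random.default_rng(seed)
    z = _standardized_columns(abundance.to_numpy(dtype=float), method)
    observed = z.T @ z  # Pearson of rank-transformed columns == Spearman
    if n_iter > 0:
        null_sum = np.zeros_like(observed)
        n, p = z.shape
        for _ in range(n_iter):
            perm = np.empty_like(z)
            for k in range(p):
                perm[:, k] = z[rng.permutation(n), k]
            null_sum += z.T @ perm
        corrected = observed - null_sum / n_iter
    else:
        corrected = observed
    np.fill_diagonal(corrected, np.nan)
    return pd.DataFrame(corrected, index=abundance.columns,
                        columns=abundance.columns)


def connectedness(corrected: pd.DataFrame) -> Connectedness:
    """Mean strictly-positive / strictly-negative corrected correlation per taxon.

    A taxon with no positive (negative) partners gets 0 for that side.
    """
    m = corrected.to_numpy(dtype=float)
    pos = np.where(np.isnan(m) | (m <= 0), np.nan, m)
    neg = np.where(np.isnan(m) | (m >= 0), np.nan, m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        c_pos = np.nan_to_num(np.nanmean(pos, axis=1))
        c_neg = np.nan_to_num(np.nanmean(neg, axis=1))
    return Connectedness(
        c_pos=pd.Series(c_pos, index=corrected.index),
        c_neg=pd.Series(c_neg, index=corrected.index),
    )


def sample_cohesion(abundance: pd.DataFrame, conn: Connectedness) -> CohesionResult:
    """Abundance-weighted cohesion per sample (samples x taxa input).

    C_pos = sum_j a_ij c_pos_j, C_neg likewise; NPC = |C_neg| / C_pos,
    undefined (NaN) where C_pos is 0.
    """
    a = abundance.to_numpy(dtype=float)
    cp = a @ conn.c_pos.reindex(abundance.columns).to_numpy()
    cn = a @ conn.c_neg.reindex(abundance.columns).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        npc = np.where(cp > 0, np.abs(cn) / cp, np.nan)
    idx = abundance.index
    return CohesionResult(
        c_pos=pd.Series(cp, index=idx),
        c_neg=pd.Series(cn, index=idx),
        npc=pd.Series(npc, index=idx),
    )
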