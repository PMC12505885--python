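"""Signed co-occurrence network construction.

Pipeline: Spearman rank correlation across samples for every taxon pair,
Benjamini-Hochberg FDR adjustment of the two-sided p-values, and automatic
correlation-threshold selection by random matrix theory (RMT). The RMT
criterion scans a threshold grid and keeps the smallest threshold at which
the nearest-neighbour spacing distribution (NNSD) of the unfolded
eigenvalues of the thresholded correlation matrix follows Poisson
statistics (uncorrelated, signal-dominated spectrum) rather than the
Wigner-Dyson / GOE statistics typical of correlated noise. An edge enters
the network only if it passes both the RMT threshold and the FDR cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .containers import AbundanceTable

logger = logging.getLogger(__name__)

MIN_EIGENVALUES = 20


class NoRMTTransitionError(RuntimeError):
    """No threshold on the grid showed a persistent Poisson-accepting NNSD."""

    def __init__(self, message: str, trace: pd.DataFrame | None = None):
        super().__init__(message)
        self.trace = trace


@dataclass
class CorrelationResult:
    """Pairwise Spearman correlations with raw and BH-adjusted p-values."""

    taxa: pd.Index
    rho: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        for name in ("rho", "p_raw", "p_adj"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")


@dataclass
class SpacingFit:
    """Goodness of fit of an unfolded NNSD against Poisson and GOE laws."""

    threshold: float
    n_retained_nodes: int
    spacings: np.ndarray
    chi2_poisson: float
    p_poisson: float
    chi2_goe: float
    p_goe: float
    degenerate: bool = False


@dataclass
class CooccurrenceNetwork:
    """Signed, undirected taxa graph at a chosen correlation threshold."""

    graph: nx.Graph
    threshold: float
    alpha_fdr: float = 0.05
    diagnostics: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def taxa(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (a, b, d["weight"], d["sign"], d["p_adj"])
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "sign", "p_adj"])

    def write(self, edge_path, graphml_path=None) -> None:
        self.edge_table().to_csv(edge_path, sep="\t", index=False)
        if graphml_path is not None:
            nx.write_graphml(self.graph, graphml_path)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries are passed through and ignored for the adjustment.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def spearman_matrix(abundance: AbundanceTable | pd.DataFrame) -> CorrelationResult:
    """Spearman correlation across samples for all taxon pairs.

    Ties get average ranks; two-sided p-values use the t approximation.
    Constant taxon rows yield undefined correlations, recorded as NaN and
    excluded from edge sets downstream.
    """
    data = abundance.data if isinstance(abundance, AbundanceTable) else abundance
    n_samples = data.shape[1]
    if n_samples < 3:
        raise ValueError("need at least 3 samples for Spearman correlation")
    values = data.to_numpy(dtype=float)
    constant = np.ptp(values, axis=1) == 0
    if constant.any():
        logger.warning(
            "%d constant taxon rows: correlations recorded as missing (%s)",
            constant.sum(), list(data.index[constant][:5]),
        )
    # Spearman = Pearson on average ranks; two-sided p from the
    # t-approximation with n-2 degrees of freedom
    ranks = stats.rankdata(values, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
        tstat = rho * np.sqrt((n_samples - 2) / np.clip(1.0 - rho**2,
                                                        1e-300, None))
        p_raw = 2.0 * stats.t.sf(np.abs(tstat), df=n_samples - 2)
    p_raw[np.abs(rho) >= 1.0 - 1e-14] = 0.0
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    p_raw[constant, :] = np.nan
    p_raw[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p_raw, 0.0)

    iu = np.triu_indices(len(data.index), k=1)
    p_adj = np.ones_like(p_raw)
    adj_upper = bh_adjust(p_raw[iu])
    p_adj[iu] = adj_upper
    p_adj = np.triu(p_adj, 1) + np.triu(p_adj, 1).T
    p_adj[np.isnan(p_raw)] = np.nan
    np.fill_diagonal(p_adj, 0.0)
    return CorrelationResult(taxa=data.index, rho=rho, p_raw=p_raw, p_adj=p_adj)


# ---------------------------------------------------------------------------
# NNSD / RMT machinery


def _unfold(eigenvalues: np.ndarray) -> np.ndarray:
    """Unfold eigenvalues by a cubic spline fit to the empirical spectral CDF.

    Degenerate (tied) eigenvalues are collapsed to a single level first.
    Returns the unfolded levels; spacings between consecutive levels have
    mean ~1 if the fit is adequate.
    """
    ev = np.sort(np.asarray(eigenvalues, dtype=float))
    # collapse exact/near-exact degeneracies
    uniq = [ev[0]]
    for e in ev[1:]:
        if e - uniq[-1] > 1e-10 * max(1.0, abs(e)):
            uniq.append(e)
    ev = np.asarray(uniq)
    n = ev.size
    if n < 3:
        return np.arange(n, dtype=float)
    counts = np.arange(1, n + 1, dtype=float)
    n_knots = max(1, min(20, n // 15))
    qs = np.linspace(0, 1, n_knots + 2)[1:-1]
    knots = np.quantile(ev, qs)
    knots = np.unique(knots[(knots > ev[0]) & (knots < ev[-1])])
    try:
        spl = interpolate.LSQUnivariateSpline(ev, counts, knots, k=3)
        return spl(ev)
    except Exception:  # pragma: no cover - ill-conditioned knot layout
        coeff = np.polyfit(ev, counts, deg=min(5, n - 1))
        return np.polyval(coeff, ev)


def _chi2_gof(spacings: np.ndarray, cdf, n_bins: int) -> tuple[float, float]:
    """Chi-square GOF of spacings against a reference spacing law.

    Equal-width bins over [0, max] (last bin open to infinity), merged from
    the left until each expected count is >= 5.
    """
    d = spacings
    n = d.size
    edges = np.linspace(0.0, d.max(), n_bins + 1)
    edges[-1] = np.inf
    probs = np.diff(cdf(edges))
    obs, _ = np.histogram(d, bins=np.r_[edges[:-1], np.inf])
    exp = probs * n

    # merge adjacent bins until expected >= 5
    m_obs, m_exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= 5.0:
            m_obs.append(acc_o)
            m_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if m_exp:
            m_obs[-1] += acc_o
            m_exp[-1] += acc_e
        else:
            m_obs, m_exp = [acc_o], [acc_e]
    m_obs = np.asarray(m_obs)
    m_exp = np.asarray(m_exp)
    if m_obs.size < 2:
        return np.nan, np.nan
    chi2 = float(np.sum((m_obs - m_exp) ** 2 / m_exp))
    dof = m_obs.size - 1
    return chi2, float(stats.chi2.sf(chi2, dof))


def _poisson_cdf(d):
    d = np.asarray(d, dtype=float)
    return np.where(np.isinf(d), 1.0, 1.0 - np.exp(-np.clip(d, 0, None)))


def _goe_cdf(d):
    """Wigner surmise CDF: P(d) = (pi d / 2) exp(-pi d^2 / 4)."""
    d = np.asarray(d, dtype=float)
    return np.where(np.isinf(d), 1.0,
                    1.0 - np.exp(-math.pi * np.clip(d, 0, None) ** 2 / 4.0))


def nnsd_fit(
    eigenvalues: np.ndarray,
    n_bins: int | None = None,
    threshold: float = float("nan"),
) -> SpacingFit:
    """Fit the nearest-neighbour spacing distribution of a spectrum.

    Eigenvalues are unfolded by a smoothing-spline fit to the empirical
    spectral CDF; spacings on the unfolded scale are tested by chi-square
    against the Poisson law exp(-d) and the Wigner surmise.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size < MIN_EIGENVALUES:
        raise ValueError(
            f"need >= {MIN_EIGENVALUES} eigenvalues for an NNSD fit, got {ev.size}"
        )
    if np.ptp(ev) == 0:
        return SpacingFit(threshold, ev.size, np.array([]), np.nan, np.nan,
                          np.nan, np.nan, degenerate=True)
    unfolded = _unfold(ev)
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    if spacings.size < 10:
        return SpacingFit(threshold, ev.size, spacings, np.nan, np.nan,
                          np.nan, np.nan, degenerate=True)
    mean_sp = spacings.mean()
    degenerate = not (0.8 <= mean_sp <= 1.2)
    spacings = spacings / mean_sp  # GOF tests compare shape at unit mean
    if n_bins is None:
        n_bins = int(np.ceil(np.log2(spacings.size))) + 1  # Sturges
    chi2_p, p_p = _chi2_gof(spacings, _poisson_cdf, n_bins)
    chi2_g, p_g = _chi2_gof(spacings, _goe_cdf, n_bins)
    return SpacingFit(threshold, ev.size, spacings, chi2_p, p_p, chi2_g, p_g,
                      degenerate=degenerate)


def _thresholded_spectrum(rho: np.ndarray, s: float) -> tuple[np.ndarray, int]:
    """Eigenvalues of the thresholded correlation matrix, isolates dropped."""
    m = np.where(np.isnan(rho), 0.0, rho).copy()
    np.fill_diagonal(m, 0.0)
    m[np.abs(m) < s] = 0.0
    keep = np.flatnonzero(np.any(m != 0.0, axis=1))
    if keep.size == 0:
        return np.array([]), 0
    sub = m[np.ix_(keep, keep)]
    np.fill_diagonal(sub, 1.0)
    return np.linalg.eigvalsh(sub), keep.size


def select_rmt_threshold(
    corr: CorrelationResult,
    grid_start: float = 0.30,
    grid_stop: float = 0.99,
    grid_step: float = 0.01,
    alpha: float = 0.05,
    persistence: int = 3,
) -> tuple[float, pd.DataFrame]:
    """Scan a threshold grid for the GOE -> Poisson NNSD transition.

    Returns the smallest threshold whose NNSD accepts the Poisson law
    (p > alpha) and keeps accepting it for ``persistence`` consecutive grid
    points, together with the full diagnostic trace. Raises
    :class:`NoRMTTransitionError` if no such threshold exists.
    """
    grid = np.arange(grid_start, grid_stop + 1e-9, grid_step)
    records = []
    for s in grid:
        ev, n_nodes = _thresholded_spectrum(corr.rho, s)
        if ev.size < MIN_EIGENVALUES:
            records.append((s, n_nodes, np.nan, np.nan, np.nan, np.nan, True))
            continue
        fit = nnsd_fit(ev, threshold=s)
        records.append((s, n_nodes, fit.chi2_poisson, fit.p_poisson,
                        fit.chi2_goe, fit.p_goe, fit.degenerate))
    trace = pd.DataFrame(
        records,
        columns=["threshold", "n_nodes", "chi2_poisson", "p_poisson",
                 "chi2_goe", "p_goe", "degenerate"],
    )
    accept = (trace["p_poisson"] > alpha).to_numpy()
    for i in range(len(grid) - persistence + 1):
        if accept[i : i + persistence].all():
            return float(grid[i]), trace
    raise NoRMTTransitionError(
        "no RMT transition found: no threshold shows a persistent "
        "Poisson-accepting NNSD", trace=trace,
    )


def build_network(
    corr: CorrelationResult,
    threshold: float,
    alpha_fdr: float = 0.05,
    diagnostics: pd.DataFrame | None = None,
) -> CooccurrenceNetwork:
    """Network with edges where |rho| >= threshold AND p_adj < alpha_fdr.

    Isolated taxa stay in the graph as degree-0 nodes (flagged via the
    ``isolated`` node attribute); edge sign follows the correlation sign.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    g = nx.Graph()
    taxa = list(corr.taxa)
    g.add_nodes_from(taxa)
    n = len(taxa)
    iu = np.triu_indices(n, k=1)
    rho = corr.rho[iu]
    padj = corr.p_adj[iu]
    ok = (~np.isnan(rho)) & (np.abs(rho) >= threshold) & (padj < alpha_fdr)
    for i, j, r, q in zip(iu[0][ok], iu[1][ok], rho[ok], padj[ok]):
        g.add_edge(taxa[i], taxa[j], weight=float(r),
                   sign="+" if r > 0 else "-", p_adj=float(q))
    for node in g.nodes:
        g.nodes[node]["isolated"] = g.degree(node) == 0
    return CooccurrenceNetwork(graph=g, threshold=float(threshold),
                               alpha_fdr=alpha_fdr, diagnostics=diagnostics)
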