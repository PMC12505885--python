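"""Per-sample subnetworks, complexity metrics, and vulnerability.

All metrics are topological (edge signs and weights ignored): average
degree 2E/N, connectance 2E/(N(N-1)), mean local clustering, global
efficiency (mean inverse shortest-path length over ordered pairs), and
vulnerability — the maximum proportional loss of global efficiency caused
by removing a single node. Shortest paths are unweighted BFS distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path


@dataclass
class SubNetwork:
    """Induced subgraph on the taxa present (abundance > 0) in one sample."""

    sample_id: str
    graph: nx.Graph
    parent_threshold: float

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)


@dataclass
class ComplexityMetrics:
    n_nodes: int
    n_edges: int
    average_degree: float
    connectance: float
    clustering_coefficient: float
    degenerate: bool = False


@dataclass
class VulnerabilityResult:
    global_efficiency: float
    per_node_vulnerability: pd.Series
    vulnerability: float
    degenerate: bool = False


def sample_subnetwork(network, abundance_column: pd.Series) -> SubNetwork:
    """Induced subgraph on taxa with abundance strictly greater than zero."""
    g = network.graph
    missing = [t for t in g.nodes if t not in abundance_column.index]
    if missing:
        raise ValueError(
            f"abundance column not aligned to network taxa; missing {missing[:5]}"
        )
    present = [t for t in g.nodes if abundance_column[t] > 0]
    sub = g.subgraph(present).copy()
    return SubNetwork(sample_id=str(abundance_column.name), graph=sub,
                      parent_threshold=network.threshold)


def complexity_metrics(g: nx.Graph | SubNetwork) -> ComplexityMetrics:
    """Topological complexity of a graph; degree<2 local clustering counts as 0."""
    if isinstance(g, SubNetwork):
        g = g.graph
    n = g.number_of_nodes()
    e = g.number_of_edges()
    if n == 0:
        return ComplexityMetrics(0, 0, np.nan, np.nan, np.nan, degenerate=True)
    avg_deg = 2.0 * e / n
    if n < 2:
        return ComplexityMetrics(n, e, avg_deg, 0.0, 0.0, degenerate=True)
    connectance = 2.0 * e / (n * (n - 1))
    clustering = nx.average_clustering(g)  # deg<2 nodes contribute 0
    return ComplexityMetrics(n, e, avg_deg, connectance, clustering)


def _distance_matrix(g: nx.Graph) -> np.ndarray:
    nodes = list(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    rows, cols = [], []
    for a, b in g.edges:
        rows += [idx[a], idx[b]]
        cols += [idx[b], idx[a]]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return shortest_path(adj, method="D", unweighted=True)


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0  # diagonal and disconnected pairs
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(g: nx.Graph | SubNetwork) -> float:
    """E(G) = mean of 1/d(i,j) over ordered pairs; disconnected pairs add 0."""
    if isinstance(g, SubNetwork):
        g = g.graph
    if g.number_of_nodes() < 2:
        return 0.0
    return _efficiency_from_distances(_distance_matrix(g))


def vulnerability(g: nx.Graph | SubNetwork) -> VulnerabilityResult:
    """Max proportional efficiency loss over single-node removals.

    V_i = (E - E_i) / E where E_i is the efficiency of the graph without
    node i, normalized over its remaining (N-1)(N-2) ordered pairs. Graphs
    with fewer than 3 nodes, or zero efficiency, yield a degenerate record
    with vulnerability 0.
    """
    if isinstance(g, SubNetwork):
        g = g.graph
    nodes = list(g.nodes)
    n = len(nodes)
    if n < 3:
        return VulnerabilityResult(
            global_efficiency(g), pd.Series(dtype=float), 0.0, degenerate=True
        )
    idx = {v: i for i, v in enumerate(nodes)}
    rows, cols = [], []
    for a, b in g.edges:
        rows += [idx[a], idx[b]]
        cols += [idx[b], idx[a]]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).toarray()
    e_full = _efficiency_from_distances(
        shortest_path(csr_matrix(adj), method="D", unweighted=True)
    )
    if e_full == 0.0:
        return VulnerabilityResult(0.0, pd.Series(0.0, index=nodes), 0.0,
                                   degenerate=True)
    v = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        sub = adj[np.ix_(mask, mask)]
        e_i = _efficiency_from_distances(
            shortest_path(csr_matrix(sub), method="D", unweighted=True)
        )
        v[i] = (e_full - e_i) / e_full
        mask[i] = True
    per_node = pd.Series(v, index=nodes)
    return VulnerabilityResult(e_full, per_node, float(per_node.max()))


def sample_metrics_table(network, abundance: pd.DataFrame) -> pd.DataFrame:
    """Complexity + stability metrics for every sample column of ``abundance``.

    Rows are samples; taxa not in the network are ignored (the network may
    have been prevalence-filtered).
    """
    rows = []
    net_taxa = [t for t in network.graph.nodes]
    for sid in abundance.columns:
        col = abundance[sid].reindex(net_taxa).fillna(0.0)
        col.name = sid
        sub = sample_subnetwork(network, col)
        cm = complexity_metrics(sub)
        vr = vulnerability(sub)
        rows.append({
            "sample_id": sid,
            "n_nodes": cm.n_nodes,
            "n_edges": cm.n_edges,
            "average_degree": cm.average_degree,
            "connectance": cm.connectance,
            "clustering": cm.clustering_coefficient,
            "global_efficiency": vr.global_efficiency,
            "vulnerability": vr.vulnerability,
            "degenerate": cm.degenerate or vr.degenerate,
        })
    return pd.DataFrame(rows).set_index("sample_id")
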