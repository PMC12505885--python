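"""Correlation matrices, BH adjustment, NNSD fits and RMT thresholds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from warmnet import (
    CorrelationResult,
    NoRMTTransitionError,
    ModuleSpec,
    bh_adjust,
    build_network,
    correlated_abundances,
    nnsd_fit,
    select_rmt_threshold,
    spearman_matrix,
)
from .conftest import make_abundance


def bh_bruteforce(p):
    """Textbook step-up definition: adj_(i) = min_{j>=i} m p_(j)/j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_textbook_example(self):
        got = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        got = bh_adjust(np.full(7, 0.2))
        assert np.allclose(got, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    def test_nan_passthrough(self):
        got = bh_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(got[1])
        assert np.allclose(got[[0, 2]], bh_adjust(np.array([0.01, 0.04])))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_matches_bruteforce_and_statsmodels(self, ps):
        p = np.asarray(ps)
        got = bh_adjust(p)
        assert np.allclose(got, bh_bruteforce(p))
        assert np.allclose(got, multipletests(p, method="fdr_bh")[1])


class TestSpearmanMatrix:
    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            spearman_matrix(make_abundance([[1, 2], [2, 1]]))

    def test_monotone_transforms(self):
        # strictly increasing transform of the same ranks -> rho 1;
        # reversed -> rho -1
        ab = make_abundance([
            [1.0, 2.0, 3.0, 4.0],
            [0.1, 4.0, 9.0, 16.0],
            [4.0, 3.0, 2.0, 1.0],
        ])
        res = spearman_matrix(ab)
        assert res.rho[0, 1] == pytest.approx(1.0)
        assert res.rho[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(res.rho), 1.0)

    def test_hand_computed_rho(self):
        # ranks of (1,2,3,4) vs (1,3,2,4): Pearson of ranks = 0.8
        ab = make_abundance([[1, 2, 3, 4], [1, 3, 2, 4]])
        res = spearman_matrix(ab)
        assert res.rho[0, 1] == pytest.approx(0.8)

    def test_constant_row_recorded_missing(self):
        ab = make_abundance([[1, 2, 3, 4], [5, 5, 5, 5], [4, 3, 2, 1]])
        res = spearman_matrix(ab)
        assert np.isnan(res.rho[0, 1]) and np.isnan(res.rho[1, 2])
        assert not np.isnan(res.rho[0, 2])

    def test_symmetry_and_padj_dominates_praw(self, default_dataset):
        table = default_dataset.tables["nematode"]
        sub = table.data.iloc[:15, :20]
        res = spearman_matrix(sub)
        assert np.allclose(res.rho, res.rho.T, equal_nan=True)
        iu = np.triu_indices(15, 1)
        ok = ~np.isnan(res.p_raw[iu])
        assert (res.p_adj[iu][ok] >= res.p_raw[iu][ok] - 1e-12).all()
        assert ((res.p_adj[iu][ok] >= 0) & (res.p_adj[iu][ok] <= 1)).all()


class TestNNSD:
    def test_too_few_eigenvalues(self):
        with pytest.raises(ValueError):
            nnsd_fit(np.array([1.0, 2.0]))

    def test_goe_spectrum_accepts_wigner(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((500, 500))
        ev = np.linalg.eigvalsh((a + a.T) / np.sqrt(2))
        fit = nnsd_fit(ev)
        assert fit.p_goe > 0.05
        assert fit.p_poisson < 1e-6
        assert not fit.degenerate

    def test_uncorrelated_spectrum_accepts_poisson(self):
        rng = np.random.default_rng(0)
        ev = np.sort(rng.uniform(0, 1, 500))
        fit = nnsd_fit(ev)
        assert fit.p_poisson > 0.05
        assert fit.p_goe < 1e-6

    def test_degenerate_spectrum_flagged(self):
        fit = nnsd_fit(np.full(30, 2.5))
        assert fit.degenerate


def planted_correlation(seed=0, n_modules=5, size=10, n_samples=200):
    mods = [ModuleSpec(tuple(range(size * i, size * (i + 1))), 0.9)
            for i in range(n_modules)]
    a = correlated_abundances(n_modules * size, n_samples, mods, seed=seed)
    df = pd.DataFrame(a, index=[f"T{i:02d}" for i in range(n_modules * size)],
                      columns=[f"S{j}" for j in range(n_samples)])
    return spearman_matrix(df), mods


class TestRMTThreshold:
    def test_planted_modules_threshold_between_scales(self):
        corr, _ = planted_correlation(seed=0)
        thr, trace = select_rmt_threshold(corr)
        noise = np.nanmax(np.abs(corr.rho[:10, 10:]))
        assert noise < thr < 0.9
        assert {"threshold", "p_poisson", "n_nodes"} <= set(trace.columns)

    def test_identity_like_matrix_has_no_transition(self):
        n = 30
        rho = np.eye(n)
        res = CorrelationResult(pd.Index([f"T{i}" for i in range(n)]),
                                rho, np.ones((n, n)), np.ones((n, n)))
        with pytest.raises(NoRMTTransitionError) as exc:
            select_rmt_threshold(res)
        assert exc.value.trace is not None


class TestBuildNetwork:
    def _corr3(self):
        rho = np.array([[1.0, 0.95, 0.50],
                        [0.95, 1.0, -0.90],
                        [0.50, -0.90, 1.0]])
        p_adj = np.array([[0.0, 0.001, 0.20],
                          [0.001, 0.0, 0.01],
                          [0.20, 0.01, 0.0]])
        return CorrelationResult(pd.Index(["a", "b", "c"]), rho,
                                 p_adj.copy(), p_adj)

    def test_conjunction_rule_by_hand(self):
        net = build_network(self._corr3(), threshold=0.8)
        edges = {tuple(sorted(e)): d["sign"]
                 for *e, d in net.graph.edges(data=True)}
        assert edges == {("a", "b"): "+", ("b", "c"): "-"}

    def test_isolates_retained_and_flagged(self):
        net = build_network(self._corr3(), threshold=0.96)
        assert set(net.graph.nodes) == {"a", "b", "c"}
        assert all(net.graph.nodes[n]["isolated"] for n in net.graph)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            build_network(self._corr3(), threshold=0.0)

    def test_edge_monotonicity(self):
        corr, _ = planted_correlation(seed=2, n_samples=60)
        prev = None
        for s in (0.3, 0.5, 0.7, 0.9):
            net = build_network(corr, s)
            edges = {tuple(sorted(e)) for e in net.graph.edges}
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_permutation_null_kills_significance(self):
        rng = np.random.default_rng(4)
        corr, _ = planted_correlation(seed=3, n_samples=100)
        # destroy dependence by permuting each taxon independently
        a = correlated_abundances(
            50, 100,
            [ModuleSpec(tuple(range(10 * i, 10 * i + 10)), 0.9)
             for i in range(5)], seed=3)
        for row in a:
            rng.shuffle(row)
        df = pd.DataFrame(a, index=[f"T{i}" for i in range(50)],
                          columns=[f"S{j}" for j in range(100)])
        res = spearman_matrix(df)
        iu = np.triu_indices(50, 1)
        frac = np.mean(res.p_adj[iu] < 0.05)
        assert frac < 0.01

    def test_export_edge_list(self, tmp_path):
        net = build_network(self._corr3(), threshold=0.8)
        net.write(tmp_path / "edges.tsv", tmp_path / "net.graphml")
        back = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
        assert set(back.columns) == {"taxon_a", "taxon_b", "rho", "sign",
                                     "p_adj"}
        assert len(back) == 2
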