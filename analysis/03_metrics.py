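#!/usr/bin/env python
"""Per-sample network complexity and stability metrics.

Extracts each sample's induced subnetwork from the parent networks built in
step 02 and computes complexity (nodes, edges, average degree, connectance,
clustering) and stability (global efficiency, vulnerability). Cohesion and
the NPC ratio are computed threshold-free from the community abundance
tables with the taxa-shuffle null model.
"""

import argparse
import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

from warmnet.cohesion import (
    connectedness,
    null_corrected_correlations,
    sample_cohesion,
)
from warmnet.containers import AbundanceTable
from warmnet.netbuild import CooccurrenceNetwork
from warmnet.netmetrics import sample_metrics_table

ROOT = Path(__file__).resolve().parents[1]


def load_network(edges_path: Path, taxa) -> CooccurrenceNetwork:
    g = nx.Graph()
    g.add_nodes_from(taxa)
    edges = pd.read_csv(edges_path, sep="\t")
    for _, r in edges.iterrows():
        g.add_edge(r["taxon_a"], r["taxon_b"], weight=r["rho"],
                   sign=r["sign"], p_adj=r["p_adj"])
    return CooccurrenceNetwork(graph=g, threshold=float("nan"))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--netdir", type=Path,
                    default=ROOT / "results" / "networks")
    ap.add_argument("--outdir", type=Path,
                    default=ROOT / "results" / "metrics")
    ap.add_argument("--n-iter", type=int, default=200)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    warnings.filterwarnings("ignore")
    args.outdir.mkdir(parents=True, exist_ok=True)

    metadata = pd.read_csv(args.datadir / "metadata.tsv", sep="\t",
                           index_col="sample_id")
    metric_frames, stab_frames = [], []
    for community in ("nematode", "protist", "whole"):
        table = AbundanceTable.from_tsv(
            args.datadir / f"abundance_{community}.tsv")
        for depth in metadata["depth"].unique():
            ids = metadata.index[metadata["depth"] == depth]
            sub = table.subset_samples(ids).prevalence_filter(0.25)
            net = load_network(
                args.netdir / f"edges_{community}_{depth}.tsv", sub.taxa)
            metrics = sample_metrics_table(net, sub.data)
            metrics.insert(0, "community", community)
            metrics.insert(1, "depth", depth)
            metric_frames.append(metrics)

            layer = table.subset_samples(ids)
            corrected = null_corrected_correlations(
                layer.data.T, n_iter=args.n_iter, seed=args.seed)
            coh = sample_cohesion(layer.data.T, connectedness(corrected))
            stab_frames.append(pd.DataFrame({
                "community": community, "depth": depth,
                "C_pos": coh.c_pos, "C_neg": coh.c_neg, "npc": coh.npc}))

    metrics = pd.concat(metric_frames)
    stability = pd.concat(stab_frames)
    metrics.to_csv(args.outdir / "sample_metrics.tsv", sep="\t")
    stability.to_csv(args.outdir / "stability.tsv", sep="\t",
                     index_label="sample_id")

    top = metrics[metrics["depth"] == metadata["depth"].unique()[0]]
    tr = metadata["treatment"]
    print("topsoil mean connectance by warming level:")
    for community, grp in top.groupby("community"):
        means = grp["connectance"].groupby(tr).mean()
        print(f"  {community}: " + "  ".join(
            f"+{lv}: {v:.3f}" for lv, v in means.items()))


if __name__ == "__main__":
    main()
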