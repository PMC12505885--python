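#!/usr/bin/env python
"""Build the six co-occurrence networks (3 communities x 2 depth layers).

For each community table the step applies the prevalence filter, computes
Spearman correlations with BH-adjusted p-values, selects the correlation
threshold by random matrix theory (NNSD transition to Poisson statistics),
and writes edge lists, GraphML files and the RMT diagnostic traces.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from warmnet.containers import AbundanceTable
from warmnet.netbuild import (
    NoRMTTransitionError,
    build_network,
    select_rmt_threshold,
    spearman_matrix,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--outdir", type=Path,
                    default=ROOT / "results" / "networks")
    ap.add_argument("--fallback-threshold", type=float, default=0.6)
    args = ap.parse_args()
    warnings.filterwarnings("ignore")
    args.outdir.mkdir(parents=True, exist_ok=True)

    metadata = pd.read_csv(args.datadir / "metadata.tsv", sep="\t",
                           index_col="sample_id")
    rows = []
    for community in ("nematode", "protist", "whole"):
        table = AbundanceTable.from_tsv(
            args.datadir / f"abundance_{community}.tsv")
        for depth in metadata["depth"].unique():
            ids = metadata.index[metadata["depth"] == depth]
            sub = table.subset_samples(ids).prevalence_filter(0.25)
            corr = spearman_matrix(sub)
            try:
                threshold, trace = select_rmt_threshold(corr)
                selected = True
            except NoRMTTransitionError as exc:
                threshold, trace = args.fallback_threshold, exc.trace
                selected = False
            net = build_network(corr, threshold, diagnostics=trace)
            tag = f"{community}_{depth}"
            net.write(args.outdir / f"edges_{tag}.tsv",
                      args.outdir / f"network_{tag}.graphml")
            if trace is not None:
                trace.to_csv(args.outdir / f"rmt_trace_{tag}.tsv", sep="\t",
                             index=False)
            neg = sum(1 for *_, d in net.graph.edges(data=True)
                      if d["sign"] == "-")
            rows.append({"community": community, "depth": depth,
                         "threshold": threshold, "rmt_selected": selected,
                         "n_nodes": net.graph.number_of_nodes(),
                         "n_edges": net.n_edges, "n_negative_edges": neg})
            print(f"{tag}: threshold={threshold:.2f} "
                  f"(RMT={'yes' if selected else 'fallback'}) "
                  f"nodes={net.graph.number_of_nodes()} edges={net.n_edges} "
                  f"({neg} negative)")
    pd.DataFrame(rows).to_csv(args.outdir / "networks_summary.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
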