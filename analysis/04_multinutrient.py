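#!/usr/bin/env python
"""Multinutrient cycling index per sample.

Standardizes the ten nutrient-pool variables (SOC, TN, TP, AP, NH4-N,
NO3-N, DOC, MBC, MBN, MBP) within each depth layer and averages the
z-scores, yielding the per-sample MNC used as the ecosystem-functioning
response in step 05.
"""

import argparse
from pathlib import Path

import pandas as pd

from warmnet import mnc_index

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "mnc")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    metadata = pd.read_csv(args.datadir / "metadata.tsv", sep="\t",
                           index_col="sample_id")
    soil = pd.read_csv(args.datadir / "soil.tsv", sep="\t",
                       index_col="sample_id")

    frames = []
    for depth in metadata["depth"].unique():
        cohort = metadata.index[metadata["depth"] == depth]
        res = mnc_index(soil, cohort=cohort)
        frames.append(pd.DataFrame({"depth": depth, "mnc": res.mnc}))
        print(f"{depth}: MNC over {len(res.mnc)} samples using "
              f"{len(res.variables_used)} variables; by warming level:")
        means = res.mnc.groupby(metadata.loc[cohort, "treatment"]).mean()
        print("   " + "  ".join(f"+{lv}: {v:+.2f}"
                                for lv, v in means.items()))
    pd.concat(frames).to_csv(args.outdir / "mnc.tsv", sep="\t",
                             index_label="sample_id")


if __name__ == "__main__":
    main()
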