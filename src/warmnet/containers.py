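"""Shared in-memory containers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

COMMUNITIES = ("nematode", "protist", "whole")

NEMATODE_GROUPS = ("bacterivore", "fungivore", "herbivore", "predator", "omnivore")
PROTIST_GROUPS = ("consumer", "parasite", "phototroph")


@dataclass
class AbundanceTable:
    """Relative-abundance table (taxa x samples) with per-taxon annotation.

    ``data`` rows are taxa, columns are sample IDs; each column holds
    relative abundances that sum to 1. ``annotation`` is indexed by taxon
    and carries ``community`` (nematode/protist) and ``functional_group``.
    """

    data: pd.DataFrame
    annotation: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.annotation is None:
            self.annotation = pd.DataFrame(
                index=self.data.index, columns=["community", "functional_group"]
            )
        if not self.data.index.equals(self.annotation.index):
            missing = self.data.index.difference(self.annotation.index)
            if len(missing):
                raise ValueError(
                    f"annotation missing {len(missing)} taxa, e.g. {list(missing[:3])}"
                )
            self.annotation = self.annotation.loc[self.data.index]
        self.data = self.data.rename_axis("taxon").rename_axis("sample_id", axis=1)
        self.annotation = self.annotation.rename_axis("taxon")

    @property
    def taxa(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def column_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def is_closed(self, tol: float = 1e-9) -> bool:
        sums = self.column_sums().to_numpy()
        return bool(np.all(np.abs(sums - 1.0) <= tol))

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.data[list(sample_ids)].copy(), self.annotation)

    def prevalence_filter(self, min_prevalence: float = 0.25) -> "AbundanceTable":
        """Drop taxa nonzero in fewer than ``min_prevalence`` of samples."""
        frac = (self.data > 0).mean(axis=1)
        keep = frac >= min_prevalence
        return AbundanceTable(self.data.loc[keep].copy(), self.annotation.loc[keep])

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat([self.annotation, self.data], axis=1)
        out.to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceTable":
        raw = pd.read_csv(path, sep="\t", index_col="taxon")
        ann_cols = [c for c in ("community", "functional_group") if c in raw.columns]
        annotation = raw[ann_cols]
        data = raw.drop(columns=ann_cols).astype(float)
        return cls(data, annotation)
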