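"""Shared in-memory containers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GENOTYPES = ("control", "mutant")
STAGES = ("oocyte", "two_cell")


@dataclass
class CountMatrix:
    """Gene x sample integer count matrix with per-sample metadata.

    ``counts`` is genes (rows) x samples (columns); ``metadata`` is indexed by
    sample id with at least ``genotype`` (control/mutant) and ``stage``
    (oocyte/two_cell) columns.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.size and not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        if self.metadata is not None:
            missing = set(self.counts.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(f"samples missing from metadata: {sorted(missing)}")
            bad = set(self.metadata["genotype"]) - set(GENOTYPES)
            if bad:
                raise ValueError(f"unknown genotypes: {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_with(self, genotype: str) -> list[str]:
        sel = self.metadata.loc[list(self.counts.columns)]
        return list(sel.index[sel["genotype"] == genotype])

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], self.metadata)

    # -- plain-text round trip ------------------------------------------------

    def write(self, counts_path: str | Path, metadata_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")

    @classmethod
    def read(cls, counts_path: str | Path, metadata_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
        return cls(counts, meta)
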