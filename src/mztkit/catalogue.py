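"""Wave catalogues: gene -> transcription-wave category maps.

Mouse preimplantation transcripts arrive in successive waves: the maternal
pool deposited in the oocyte, minor ZGA at the zygote stage, a one-cell
transient wave, major ZGA at the two-cell stage, a two-cell transient wave,
and mid-preimplantation gene activation (MGA). A catalogue assigns each gene
to exactly one of these six categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

WAVE_CATEGORIES = (
    "maternal",
    "minor_ZGA",
    "1C_transient",
    "major_ZGA",
    "2C_transient",
    "MGA",
)

#: categories whose transcripts predate major ZGA (maternal/zygote-stage pool)
EARLY_CATEGORIES = ("maternal", "minor_ZGA", "1C_transient")
#: categories activated at or after the two-cell stage
LATE_CATEGORIES = ("major_ZGA", "2C_transient", "MGA")


@dataclass(frozen=True)
class WaveCatalogue:
    """Immutable gene -> category map over the six-wave vocabulary."""

    entries: dict

    def __post_init__(self) -> None:
        bad = set(self.entries.values()) - set(WAVE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown wave categories: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries

    def category_of(self, gene_id: str) -> str:
        return self.entries[gene_id]

    def genes_in(self, category: str) -> list[str]:
        if category not in WAVE_CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return [g for g, c in self.entries.items() if c == category]

    def category_sizes(self) -> dict:
        sizes = {c: 0 for c in WAVE_CATEGORIES}
        for c in self.entries.values():
            sizes[c] += 1
        return sizes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.entries), "category": list(self.entries.values())}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_catalogue(path: str | Path) -> WaveCatalogue:
    """Read a two-column TSV (gene_id, category) into a validated catalogue.

    Duplicate gene ids and unknown category labels are rejected; an empty
    file yields an empty catalogue with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "category"}
    if not required.issubset(df.columns):
        raise ValueError(f"catalogue TSV needs columns {sorted(required)}")
    if df.empty:
        warnings.warn(f"empty wave catalogue: {path}", stacklevel=2)
        return WaveCatalogue({})
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate gene ids in catalogue: {sorted(set(dup))}")
    return WaveCatalogue(dict(zip(df["gene_id"], df["category"])))
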