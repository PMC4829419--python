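"""Cross-tabulation of differential-expression classes against wave catalogues.

Each catalogued gene lands in exactly one cell of a category x
{up, down, similar, not_in_data} table; genes absent from the (filtered)
DE result count as not_in_data. Percentages are reported as integers,
rounded half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mztkit.catalogue import WAVE_CATEGORIES, WaveCatalogue, read_catalogue  # noqa: F401

OVERLAP_COLUMNS = ("up", "down", "similar", "not_in_data", "total")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (as tables print)."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass
class OverlapTable:
    """Per-category counts of up / down / similar / not_in_data genes."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(OVERLAP_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        sums = self.table[["up", "down", "similar", "not_in_data"]].sum(axis=1)
        if not (sums == self.table["total"]).all():
            raise ValueError("cells do not sum to total")

    def write(self, path) -> None:
        out = self.table.rename(
            columns={
                "up": "Up",
                "down": "Down",
                "similar": "Similar",
                "not_in_data": "Not in our data",
                "total": "Total",
            }
        )
        out.to_csv(path, sep="\t", index_label="category")


def build_overlap_table(de_result: pd.DataFrame, catalogue: WaveCatalogue) -> OverlapTable:
    """Cross-tabulate DE classes (indexed by gene) against catalogue categories."""
    de_class = de_result["de_class"]
    rows = {}
    for cat in WAVE_CATEGORIES:
        genes = catalogue.genes_in(cat)
        counts = {"up": 0, "down": 0, "similar": 0, "not_in_data": 0}
        for g in genes:
            if g in de_class.index:
                counts[de_class.loc[g]] += 1
            else:
                counts["not_in_data"] += 1
        counts["total"] = len(genes)
        rows[cat] = counts
    table = pd.DataFrame.from_dict(rows, orient="index")[list(OVERLAP_COLUMNS)]
    table.index.name = "category"
    return OverlapTable(table)


def category_percentages(table: OverlapTable) -> pd.DataFrame:
    """Integer percent of each category's genes that are up / down / similar."""
    t = table.table
    if (t["total"] <= 0).any():
        raise ValueError("category with zero total")
    out = {}
    for col in ("up", "down", "similar"):
        out[f"pct_{col}"] = [
            round_half_away(100.0 * c / tot) for c, tot in zip(t[col], t["total"])
        ]
    return pd.DataFrame(out, index=t.index)


def coverage_stats(table: OverlapTable) -> tuple[pd.Series, float]:
    """Percent of each category present in the data, and the minimum over categories."""
    t = table.table
    if (t["total"] <= 0).any():
        raise ValueError("category with zero total")
    pct = 100.0 * (t["total"] - t["not_in_data"]) / t["total"]
    return pct.rename("pct_covered"), float(pct.min())


def summarize_overlap(table: OverlapTable) -> dict:
    """Grand totals: genes considered, genes changed (up + down), percent changed."""
    t = table.table
    total = int(t["total"].sum())
    changed = int((t["up"] + t["down"]).sum())
    return {
        "total": total,
        "changed": changed,
        "pct_changed": round_half_away(100.0 * changed / total) if total else 0,
    }


@dataclass
class StageOverlap:
    """Venn counts of up/down gene sets between two stages (e.g. oocyte vs two-cell)."""

    up_both: int
    up_a_only: int
    up_b_only: int
    down_both: int
    down_a_only: int
    down_b_only: int


def stage_overlap(de_a: pd.DataFrame, de_b: pd.DataFrame) -> StageOverlap:
    """Intersect the up sets and the down sets of two DE results."""
    sets = {}
    for direction in ("up", "down"):
        a = set(de_a.index[de_a["de_class"] == direction])
        b = set(de_b.index[de_b["de_class"] == direction])
        sets[direction] = (len(a & b), len(a - b), len(b - a))
    return StageOverlap(*sets["up"], *sets["down"])
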