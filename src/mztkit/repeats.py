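"""Repeat-element quantification from multi-mapped reads.

The quantification rule set:

* a hit counts toward a repeat only if its interval is *fully contained*
  in an annotated repeat interval;
* a multi-mapped read is assigned to a family only when its hits are
  family-concordant — the majority family accounts for more than 95% of
  hits (strict inequality) and every hit lies inside some repeat;
* family counts are normalized per sample by the total number of
  repeat-assigned reads, so per-sample profiles are compositional;
* per-family differential testing between genotypes is a Welch t-test on
  log2(normalized fraction + 1/total), BH-adjusted across families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from mztkit.mapping import AlignmentRecord

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "other")

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class RepeatConfig:
    concordance_threshold: float = 0.95  # strict: majority fraction must EXCEED this
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.concordance_threshold <= 1.0:
            raise ValueError("concordance_threshold must be in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


class RepeatAnnotation:
    """Non-overlapping genomic intervals labeled with repeat family and class.

    Intervals are 0-based half-open. Each family belongs to exactly one class
    (LINE / SINE / LTR / other); overlapping intervals on one reference are an
    invariant violation and rejected at construction.
    """

    def __init__(self, intervals: pd.DataFrame):
        required = {"reference", "start", "end", "family", "repeat_class"}
        if not required.issubset(intervals.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        df = intervals.reset_index(drop=True).copy()
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must have start < end")
        bad = set(df["repeat_class"]) - set(REPEAT_CLASSES)
        if bad:
            raise ValueError(f"unknown repeat classes: {sorted(bad)}")
        fam_classes = df.groupby("family")["repeat_class"].nunique()
        if (fam_classes > 1).any():
            raise ValueError("a family maps to more than one class")
        df = df.sort_values(["reference", "start"], kind="mergesort").reset_index(drop=True)
        for ref, sub in df.groupby("reference"):
            if (sub["end"].to_numpy()[:-1] > sub["start"].to_numpy()[1:]).any():
                raise ValueError(f"overlapping repeat intervals on {ref}")
        self.intervals = df
        self._by_ref = {
            ref: (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["family"].to_numpy(),
            )
            for ref, sub in df.groupby("reference")
        }

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def families(self) -> list[str]:
        return sorted(self.intervals["family"].unique())

    def family_class_map(self) -> dict:
        return dict(
            self.intervals.drop_duplicates("family")[["family", "repeat_class"]].to_numpy()
        )

    def containing_family(self, reference: str, start: int, end: int):
        """Family of the interval fully containing [start, end), or None."""
        if reference not in self._by_ref:
            return None
        starts, ends, fams = self._by_ref[reference]
        i = int(np.searchsorted(starts, start, side="right")) - 1
        if i >= 0 and ends[i] >= end:
            return fams[i]
        return None

    # -- plain-text round trip (6-column BED + family->class TSV) -------------

    def write(self, bed_path: str | Path, class_tsv_path: str | Path) -> None:
        bed = self.intervals.copy()
        bed["score"] = 0
        bed["strand"] = "+"
        bed[["reference", "start", "end", "family", "score", "strand"]].to_csv(
            bed_path, sep="\t", index=False, header=False
        )
        cls = self.intervals.drop_duplicates("family")[["family", "repeat_class"]]
        cls.to_csv(class_tsv_path, sep="\t", index=False)

    @classmethod
    def read(cls, bed_path: str | Path, class_tsv_path: str | Path) -> "RepeatAnnotation":
        bed = pd.read_csv(
            bed_path,
            sep="\t",
            header=None,
            names=["reference", "start", "end", "family", "score", "strand"],
        )
        classes = pd.read_csv(class_tsv_path, sep="\t")
        fam2cls = dict(zip(classes["family"], classes["repeat_class"]))
        bed["repeat_class"] = bed["family"].map(fam2cls)
        if bed["repeat_class"].isna().any():
            missing = sorted(bed.loc[bed["repeat_class"].isna(), "family"].unique())
            raise ValueError(f"families missing from class TSV: {missing}")
        return cls(bed[["reference", "start", "end", "family", "repeat_class"]])


def annotate_hits(record: AlignmentRecord, annotation: RepeatAnnotation) -> list:
    """Label each hit with the family of the repeat fully containing it.

    Partial overlap yields None — only full containment counts.
    """
    return [
        annotation.containing_family(h.reference, h.start, h.end) for h in record.hits
    ]


def concordance_assign(labels: list, config: RepeatConfig = RepeatConfig()):
    """Assign a read to a family iff its hit labels are concordant.

    Returns the majority family when (majority count / total hits) strictly
    exceeds the concordance threshold AND every hit carries a family label;
    otherwise :data:`UNASSIGNED`. Majority ties are unassigned.
    """
    if not labels:
        raise ValueError("empty label list")
    if any(lab is None for lab in labels):
        return UNASSIGNED
    counts: dict = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    top = max(counts.values())
    leaders = [f for f, c in counts.items() if c == top]
    if len(leaders) != 1:
        return UNASSIGNED
    if top / len(labels) > config.concordance_threshold:
        return leaders[0]
    return UNASSIGNED


@dataclass
class RepeatCountTable:
    """Family x sample counts plus per-sample totals and normalized fractions."""

    raw: pd.DataFrame
    normalized: pd.DataFrame = field(init=False)
    totals: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.totals = self.raw.sum(axis=0)
        if (self.totals == 0).any():
            empty = list(self.totals.index[self.totals == 0])
            warnings.warn(
                f"samples with zero repeat-assigned reads: {empty}; "
                "normalized column undefined (NaN)",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            self.normalized = self.raw / self.totals.replace(0, np.nan)

    def write(self, path: str | Path) -> None:
        out = self.raw.add_prefix("raw_").join(self.normalized.add_prefix("norm_"))
        out.to_csv(path, sep="\t", index_label="family")


def build_count_table(
    records_by_sample: dict,
    annotation: RepeatAnnotation,
    config: RepeatConfig = RepeatConfig(),
) -> RepeatCountTable:
    """Tally concordantly assigned reads into a family x sample table.

    ``records_by_sample`` maps sample id -> iterable of AlignmentRecords.
    Every annotated family appears as a row (zero rows included).
    """
    families = annotation.families
    samples = list(records_by_sample)
    raw = pd.DataFrame(
        0, index=pd.Index(families, name="family"), columns=samples, dtype=int
    )
    for sample, records in records_by_sample.items():
        for rec in records:
            fam = concordance_assign(annotate_hits(rec, annotation), config)
            if fam != UNASSIGNED:
                raw.loc[fam, sample] += 1
    if raw.to_numpy().sum() == 0:
        warnings.warn("no reads assigned to any repeat family", stacklevel=2)
    return RepeatCountTable(raw)


def class_composition(table: RepeatCountTable, annotation: RepeatAnnotation) -> pd.DataFrame:
    """Per-sample fraction of repeat reads in each class (LINE/SINE/LTR/other)."""
    fam2cls = annotation.family_class_map()
    cls = table.normalized.groupby(
        table.normalized.index.map(fam2cls).rename("repeat_class")
    ).sum()
    return cls.reindex([c for c in REPEAT_CLASSES if c in cls.index])


def test_families(
    table: RepeatCountTable,
    design: pd.Series,
    config: RepeatConfig = RepeatConfig(),
) -> pd.DataFrame:
    """Per-family differential test between mutant and control samples.

    Welch t-test on log2(normalized fraction + 1/per-sample-total); the
    pseudo-count is scale-aware and avoids log(0). Two-sided p-values are
    BH-adjusted across families; a family is significant iff padj < alpha.
    """
    from mztkit.de import bh_adjust

    design = design.reindex(table.raw.columns)
    ctrl = list(design.index[design == "control"])
    mut = list(design.index[design == "mutant"])
    if len(ctrl) < 2 or len(mut) < 2:
        raise ValueError("need >=2 samples per group")
    pseudo = 1.0 / table.totals
    logf = np.log2(table.normalized.add(pseudo, axis=1))
    rows = []
    for fam in table.raw.index:
        a = logf.loc[fam, mut].to_numpy(dtype=float)
        b = logf.loc[fam, ctrl].to_numpy(dtype=float)
        log2fc = a.mean() - b.mean()
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            p = 1.0  # both groups constant and equal: no evidence
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append((fam, log2fc, p))
    out = pd.DataFrame(rows, columns=["family", "log2fc", "p"]).set_index("family")
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["padj"] < config.alpha
    return out
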