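"""Repeat quantification: containment labeling, concordance, tallies, DE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mztkit.de import bh_adjust
from mztkit.mapping import AlignmentRecord, Hit
from mztkit.repeats import (
    UNASSIGNED,
    RepeatAnnotation,
    RepeatConfig,
    RepeatCountTable,
    annotate_hits,
    build_count_table,
    class_composition,
    concordance_assign,
    test_families as run_family_de,
)


def record(read_id, *hits):
    return AlignmentRecord(read_id, tuple(Hit(*h) for h in hits))


class TestAnnotateHits:
    def test_contained_hit_labeled(self, toy_annotation):
        rec = record("r", ("chr1", 100, 149, "+", 0))
        assert annotate_hits(rec, toy_annotation) == ["L1"]

    def test_straddling_hit_unlabeled(self, toy_annotation):
        rec = record("r", ("chr1", 80, 129, "+", 0))
        assert annotate_hits(rec, toy_annotation) == [None]

    def test_exact_interval_match_labeled(self, toy_annotation):
        rec = record("r", ("chr2", 10, 200, "+", 0))
        assert annotate_hits(rec, toy_annotation) == ["L1"]

    def test_unannotated_reference_unlabeled(self, toy_annotation):
        rec = record("r", ("chrX", 100, 149, "+", 0))
        assert annotate_hits(rec, toy_annotation) == [None]

    def test_hit_past_interval_end_unlabeled(self, toy_annotation):
        rec = record("r", ("chr1", 380, 429, "+", 0))
        assert annotate_hits(rec, toy_annotation) == [None]


class TestAnnotationInvariants:
    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RepeatAnnotation(
                pd.DataFrame(
                    {
                        "reference": ["chr1", "chr1"],
                        "start": [0, 50],
                        "end": [100, 150],
                        "family": ["L1", "B1"],
                        "repeat_class": ["LINE", "SINE"],
                    }
                )
            )

    def test_family_with_two_classes_rejected(self):
        with pytest.raises(ValueError, match="class"):
            RepeatAnnotation(
                pd.DataFrame(
                    {
                        "reference": ["chr1", "chr1"],
                        "start": [0, 200],
                        "end": [100, 300],
                        "family": ["L1", "L1"],
                        "repeat_class": ["LINE", "SINE"],
                    }
                )
            )

    def test_bed_round_trip(self, toy_annotation, tmp_path):
        bed, cls = tmp_path / "r.bed", tmp_path / "r_classes.tsv"
        toy_annotation.write(bed, cls)
        back = RepeatAnnotation.read(bed, cls)
        pd.testing.assert_frame_equal(back.intervals, toy_annotation.intervals)


def oracle_concordance(labels, threshold):
    """Brute-force majority/fraction computation."""
    if any(lab is None for lab in labels):
        return UNASSIGNED
    best, best_n = None, -1
    tie = False
    for fam in set(labels):
        n = sum(1 for lab in labels if lab == fam)
        if n > best_n:
            best, best_n, tie = fam, n, False
        elif n == best_n:
            tie = True
    if tie or best_n / len(labels) <= threshold:
        return UNASSIGNED
    return best


class TestConcordance:
    def test_unanimous_assigned(self):
        assert concordance_assign(["L1"] * 20) == "L1"

    def test_exact_95_percent_is_unassigned(self):
        # 19/20 = 95% does NOT exceed the strict threshold
        assert concordance_assign(["L1"] * 19 + ["B1"]) == UNASSIGNED

    def test_49_of_50_assigned(self):
        assert concordance_assign(["L1"] * 49 + ["B1"]) == "L1"

    def test_any_unlabeled_hit_unassigns(self):
        assert concordance_assign(["L1"] * 99 + [None]) == UNASSIGNED

    def test_empty_labels_error(self):
        with pytest.raises(ValueError):
            concordance_assign([])

    @given(
        st.lists(st.sampled_from(["L1", "B1", "MT", None]), min_size=1, max_size=60),
        st.floats(0.5, 0.99),
    )
    @settings(max_examples=300, derandomize=True)
    def test_matches_brute_force_oracle(self, labels, threshold):
        config = RepeatConfig(concordance_threshold=threshold)
        assert concordance_assign(labels, config) == oracle_concordance(labels, threshold)

    @given(st.lists(st.sampled_from(["L1", "B1", "MT"]), min_size=1, max_size=40))
    @settings(max_examples=200, derandomize=True)
    def test_lowering_threshold_never_unassigns(self, labels):
        hi = concordance_assign(labels, RepeatConfig(concordance_threshold=0.95))
        lo = concordance_assign(labels, RepeatConfig(concordance_threshold=0.60))
        if hi != UNASSIGNED:
            assert lo == hi


class TestCountTable:
    def _records(self, fams, annotation):
        # one single-hit record per family label, fully contained in a copy
        recs = []
        for i, fam in enumerate(fams):
            iv = annotation.intervals.query("family == @fam").iloc[0]
            recs.append(record(f"r{i}", ("chr1", int(iv.start), int(iv.start) + 30, "+", 0)))
        return recs

    @pytest.fixture
    def two_family_annotation(self):
        return RepeatAnnotation(
            pd.DataFrame(
                {
                    "reference": ["chr1", "chr1"],
                    "start": [0, 500],
                    "end": [400, 900],
                    "family": ["A", "B"],
                    "repeat_class": ["LINE", "SINE"],
                }
            )
        )

    def test_even_split_normalizes_to_half(self, two_family_annotation):
        recs = self._records(["A"] * 50 + ["B"] * 50, two_family_annotation)
        table = build_count_table({"s1": recs}, two_family_annotation)
        assert table.raw.loc["A", "s1"] == 50
        assert table.normalized.loc["A", "s1"] == pytest.approx(0.5)
        assert table.normalized["s1"].sum() == pytest.approx(1.0)

    def test_unassigned_reads_not_counted(self, two_family_annotation):
        recs = self._records(["A"] * 10, two_family_annotation)
        # straddling record: not contained, hence unassigned
        recs.append(record("straddle", ("chr1", 390, 439, "+", 0)))
        # discordant record: one hit per family
        recs.append(
            record("discord", ("chr1", 0, 30, "+", 0), ("chr1", 500, 530, "+", 0))
        )
        table = build_count_table({"s1": recs}, two_family_annotation)
        assert table.raw["s1"].sum() == 10

    def test_no_assigned_reads_warns(self, two_family_annotation):
        with pytest.warns(UserWarning):
            table = build_count_table(
                {"s1": [record("r", ("chrX", 0, 30, "+", 0))]}, two_family_annotation
            )
        assert table.raw["s1"].sum() == 0

    def test_raw_columns_sum_to_totals(self, two_family_annotation):
        rng = np.random.default_rng(2)
        samples = {}
        expected = {}
        for s in ("s1", "s2", "s3"):
            fams = list(rng.choice(["A", "B"], size=rng.integers(5, 30)))
            samples[s] = self._records(fams, two_family_annotation)
            expected[s] = len(fams)
        table = build_count_table(samples, two_family_annotation)
        for s, n in expected.items():
            assert table.totals[s] == n
            assert table.raw[s].sum() == n


class TestComposition:
    def test_single_class_fraction_one(self):
        raw = pd.DataFrame({"s1": [30, 20]}, index=pd.Index(["A", "B"], name="family"))
        ann = RepeatAnnotation(
            pd.DataFrame(
                {
                    "reference": ["c", "c"],
                    "start": [0, 200],
                    "end": [100, 300],
                    "family": ["A", "B"],
                    "repeat_class": ["LINE", "LINE"],
                }
            )
        )
        comp = class_composition(RepeatCountTable(raw), ann)
        assert comp.loc["LINE", "s1"] == pytest.approx(1.0)

    def test_known_fractions(self):
        raw = pd.DataFrame(
            {"s1": [92, 3, 5]}, index=pd.Index(["L", "S", "R"], name="family")
        )
        ann = RepeatAnnotation(
            pd.DataFrame(
                {
                    "reference": ["c"] * 3,
                    "start": [0, 200, 400],
                    "end": [100, 300, 500],
                    "family": ["L", "S", "R"],
                    "repeat_class": ["LINE", "SINE", "LTR"],
                }
            )
        )
        comp = class_composition(RepeatCountTable(raw), ann)
        assert comp["s1"].tolist() == pytest.approx([0.92, 0.03, 0.05])

    def test_two_route_equality_with_family_sums(self, divergent_genome):
        _, annotation, _, _ = divergent_genome
        rng = np.random.default_rng(8)
        raw = pd.DataFrame(
            rng.integers(0, 100, size=(len(annotation.families), 4)),
            index=pd.Index(annotation.families, name="family"),
            columns=[f"s{i}" for i in range(4)],
        )
        table = RepeatCountTable(raw)
        comp = class_composition(table, annotation)
        fam2cls = annotation.family_class_map()
        for cls in comp.index:
            fams = [f for f in annotation.families if fam2cls[f] == cls]
            expected = table.normalized.loc[fams].sum(axis=0)
            assert np.allclose(comp.loc[cls], expected)
        assert np.allclose(comp.sum(axis=0), 1.0)


class TestFamilyTests:
    def _table(self, rng, n_per_group, line_fold=1.0, depth=2000):
        fams = ["LINE_a", "SINE_b", "LTR_c", "other_d"]
        weights = np.array([0.1, 0.4, 0.3, 0.2])
        cols = {}
        for i in range(n_per_group):
            cols[f"control_{i}"] = rng.poisson(weights * depth)
        w_mut = weights.copy()
        w_mut[0] *= line_fold
        for i in range(n_per_group):
            cols[f"mutant_{i}"] = rng.poisson(w_mut / w_mut.sum() * depth)
        raw = pd.DataFrame(cols, index=pd.Index(fams, name="family"))
        design = pd.Series(
            ["control"] * n_per_group + ["mutant"] * n_per_group, index=raw.columns
        )
        return RepeatCountTable(raw), design

    def test_planted_twofold_line_recovered(self):
        rng = np.random.default_rng(4)
        table, design = self._table(rng, 8, line_fold=2.0)
        res = run_family_de(table, design)
        assert bool(res.loc["LINE_a", "significant"])
        # compositional expectation: 2 / (1 + 0.1) after renormalization
        assert res.loc["LINE_a", "log2fc"] == pytest.approx(np.log2(2 / 1.1), abs=0.25)

    def test_single_family_bh_is_identity(self):
        raw = pd.DataFrame(
            {"c1": [10], "c2": [12], "m1": [30], "m2": [28]},
            index=pd.Index(["L1"], name="family"),
        )
        design = pd.Series(
            ["control", "control", "mutant", "mutant"], index=raw.columns
        )
        res = run_family_de(RepeatCountTable(raw), design)
        assert res["padj"].iloc[0] == pytest.approx(res["p"].iloc[0])

    def test_too_few_samples_rejected(self):
        raw = pd.DataFrame(
            {"c1": [10], "m1": [30], "m2": [28]}, index=pd.Index(["L1"], name="family")
        )
        design = pd.Series(["control", "mutant", "mutant"], index=raw.columns)
        with pytest.raises(ValueError):
            run_family_de(RepeatCountTable(raw), design)

    def test_permuted_labels_rarely_significant(self):
        """Label-permutation null: false alarms in <=5% of permutations."""
        rng = np.random.default_rng(12)
        table, _ = self._table(rng, 8, line_fold=1.0)
        n_sig = 0
        n_perm = 100
        labels = np.array(["control"] * 8 + ["mutant"] * 8)
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            design = pd.Series(perm, index=table.raw.columns)
            res = run_family_de(table, design)
            n_sig += int(res["significant"].any())
        assert n_sig <= 5


def test_zero_total_sample_flagged():
    raw = pd.DataFrame(
        {"s1": [5, 5], "s2": [0, 0]}, index=pd.Index(["A", "B"], name="family")
    )
    with pytest.warns(UserWarning, match="zero repeat"):
        table = RepeatCountTable(raw)
    assert table.normalized["s2"].isna().all()
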