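"""Differential expression: size factors, filters, NB test, BH, structure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mztkit.containers import CountMatrix
from mztkit.de import (
    DEConfig,
    bh_adjust,
    classify_de,
    cluster_samples,
    filter_genes,
    linkage_to_newick,
    nb_test,
    normalize_to_housekeeping,
    normalized_counts,
    pca_samples,
    run_de,
    size_factors,
    spearman_distance,
)


def matrix_from(counts_dict, genotypes=None):
    counts = pd.DataFrame(counts_dict)
    counts.index = [f"g{i}" for i in range(len(counts))]
    if genotypes is None:
        genotypes = ["control"] * len(counts.columns)
    meta = pd.DataFrame(
        {"genotype": genotypes, "stage": "two_cell"}, index=counts.columns
    )
    return CountMatrix(counts, meta)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        assert np.allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_gets_double_factor(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        f = size_factors(counts)
        assert f["s2"] / f["s1"] == pytest.approx(2.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(50, 6)), columns=[f"s{i}" for i in range(6)]
        )
        # oracle: s_j = median_i K_ij / (prod_j K_ij)^(1/m), genes all-positive;
        # the geometric mean is computed in log space to avoid overflow
        arr = counts.to_numpy(dtype=float)
        geo = np.exp(np.log(arr).mean(axis=1))
        expected = np.median(arr / geo[:, None], axis=0)
        assert np.allclose(size_factors(counts), expected)

    def test_gene_order_invariant(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(40, 4)), columns=list("abcd")
        )
        counts.iloc[:10] += 1
        shuffled = counts.sample(frac=1.0, random_state=3)
        assert np.allclose(size_factors(counts), size_factors(shuffled))

    def test_no_all_positive_gene_errors(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError):
            size_factors(counts)

    def test_library_scaling_removed_by_normalization(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.integers(1, 300, size=(200, 3)), columns=list("abc")
        )
        scaled = counts.copy()
        scaled["c"] = counts["c"] * 3
        norm = normalized_counts(counts)
        norm_scaled = normalized_counts(scaled)
        # size factors are defined up to a common scale (the geometric-mean
        # reference shifts); the normalized PROFILE of the scaled sample is
        # unchanged, i.e. scaling is absorbed up to one constant
        ratio = norm_scaled["c"] / norm["c"]
        assert np.allclose(ratio, ratio.iloc[0])
        profile = norm_scaled["c"] / norm_scaled["c"].sum()
        assert np.allclose(profile, norm["c"] / norm["c"].sum())


class TestFilterGenes:
    def test_zero_filter_then_top_fraction(self):
        # 10 genes, 2 all-zero -> 8 remain -> ceil(0.6 * 8) = 5 retained
        counts = {
            "s1": [0, 0, 10, 20, 30, 40, 50, 60, 70, 80],
            "s2": [0, 0, 10, 20, 30, 40, 50, 60, 70, 80],
        }
        filtered = filter_genes(matrix_from(counts))
        assert len(filtered.gene_ids) == 5
        assert list(filtered.gene_ids) == ["g5", "g6", "g7", "g8", "g9"]

    def test_ties_broken_by_gene_id(self):
        counts = {"s1": [5] * 10, "s2": [5] * 10}
        filtered = filter_genes(matrix_from(counts))
        assert list(filtered.gene_ids) == sorted([f"g{i}" for i in range(6)])

    def test_single_nonzero_gene_retained(self):
        filtered = filter_genes(matrix_from({"s1": [0, 7], "s2": [0, 3]}))
        assert list(filtered.gene_ids) == ["g1"]

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            filter_genes(matrix_from({"s1": [0, 0], "s2": [0, 0]}))


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        # p_(i) * m / i, then running minimum from the largest rank down
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_matches_hand_oracle_and_dominates_p(self, p):
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        got = bh_adjust(p)
        assert np.allclose(got, adj)
        assert (got >= p - 1e-12).all()


class TestClassify:
    @pytest.mark.parametrize(
        "log2fc,padj,expected",
        [
            (1.0, 0.01, "up"),  # boundary inclusive
            (2.5, 0.049, "up"),
            (-1.0, 0.01, "down"),
            (0.0, 0.5, "similar"),
            (-1.2, 0.2, "similar"),  # fails the FDR gate
            (0.99, 0.001, "similar"),  # fails the fold-change threshold
        ],
    )
    def test_rule_application(self, log2fc, padj, expected):
        assert classify_de([log2fc], [padj])[0] == expected

    @given(
        st.floats(-5, 5, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_partition_exhaustive_and_exclusive(self, log2fc, padj):
        out = classify_de([log2fc], [padj])
        assert out[0] in {"up", "down", "similar"}

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_de([np.nan], [0.5])


class TestNBTest:
    def test_identical_groups_null(self):
        vals = [10, 14, 9, 12]
        counts = pd.DataFrame(
            {"c1": vals, "c2": vals, "m1": vals, "m2": vals},
            index=[f"g{i}" for i in range(4)],
        )
        design = pd.Series(["control", "control", "mutant", "mutant"], index=counts.columns)
        res = nb_test(counts, size_factors(counts), design)
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_degenerate_design_rejected(self):
        counts = pd.DataFrame({"c1": [5], "c2": [6], "m1": [7]}, index=["g0"])
        design = pd.Series(["control", "control", "mutant"], index=counts.columns)
        with pytest.raises(ValueError):
            nb_test(counts, pd.Series(1.0, index=counts.columns), design)

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(7)
        G, n = 300, 8
        mu = np.full(G, 100.0)
        eff = np.ones(G)
        eff[:30] = 4.0
        a = 0.1
        ctrl = rng.negative_binomial(1 / a, 1 / (1 + a * mu[:, None]), size=(G, n))
        mut = rng.negative_binomial(
            1 / a, 1 / (1 + a * (mu * eff)[:, None]), size=(G, n)
        )
        counts = pd.DataFrame(
            np.hstack([ctrl, mut]),
            index=[f"g{i}" for i in range(G)],
            columns=[f"c{i}" for i in range(n)] + [f"m{i}" for i in range(n)],
        )
        design = pd.Series(["control"] * n + ["mutant"] * n, index=counts.columns)
        res = nb_test(counts, size_factors(counts), design)
        padj = bh_adjust(res["p"])
        assert (padj[:30] < 0.05).mean() >= 0.9
        assert res["log2fc"].iloc[:30].median() == pytest.approx(2.0, abs=0.5)


class TestHousekeeping:
    def test_unit_housekeeping_is_identity(self):
        expr = pd.DataFrame({"s1": [1.0, 5.0], "s2": [1.0, 7.0]}, index=["hk", "g"])
        out = normalize_to_housekeeping(expr, ["hk"])
        pd.testing.assert_frame_equal(out, expr)

    def test_geometric_mean_divisor(self):
        expr = pd.DataFrame(
            {"s1": [2.0, 4.0, 8.0, 40.0]}, index=["hk1", "hk2", "hk3", "g"]
        )
        out = normalize_to_housekeeping(expr, ["hk1", "hk2", "hk3"])
        assert out.loc["g", "s1"] == pytest.approx(10.0)

    def test_sample_scaling_cancels(self):
        expr = pd.DataFrame(
            {"s1": [2.0, 8.0, 40.0]}, index=["hk1", "hk2", "g"]
        )
        out1 = normalize_to_housekeeping(expr, ["hk1", "hk2"])
        out2 = normalize_to_housekeeping(expr * 13.0, ["hk1", "hk2"])
        pd.testing.assert_frame_equal(out1, out2)

    def test_nonpositive_housekeeping_rejected(self):
        expr = pd.DataFrame({"s1": [0.0, 5.0]}, index=["hk", "g"])
        with pytest.raises(ValueError):
            normalize_to_housekeeping(expr, ["hk"])


class TestSampleStructure:
    def test_duplicated_samples_merge_first(self):
        rng = np.random.default_rng(5)
        base = rng.integers(1, 200, size=100).astype(float)
        norm = pd.DataFrame(
            {
                "a": base,
                "b": base,  # duplicate of a
                "c": rng.permutation(base),
                "d": rng.integers(1, 200, size=100).astype(float),
            }
        )
        Z, labels = cluster_samples(norm)
        # first merge joins the two zero-distance duplicates
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_transform_leaves_distances_unchanged(self):
        rng = np.random.default_rng(6)
        norm = pd.DataFrame(rng.random(size=(80, 4)) * 100, columns=list("abcd"))
        d1 = spearman_distance(norm)
        transformed = norm.copy()
        transformed["a"] = np.exp(norm["a"] / 20.0)  # strictly increasing
        d2 = spearman_distance(transformed)
        assert np.allclose(d1.to_numpy(), d2.to_numpy())

    def test_too_few_samples_rejected(self):
        norm = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError):
            cluster_samples(norm)
        with pytest.raises(ValueError):
            pca_samples(norm)

    def test_newick_has_all_leaves(self):
        rng = np.random.default_rng(9)
        norm = pd.DataFrame(rng.random(size=(50, 5)) * 10, columns=list("abcde"))
        Z, _ = cluster_samples(norm)
        nwk = linkage_to_newick(Z, list(norm.columns))
        assert nwk.endswith(";")
        for leaf in norm.columns:
            assert leaf in nwk

    def test_pca_duplicated_samples_coincide(self):
        rng = np.random.default_rng(10)
        base = rng.random(60) * 50
        norm = pd.DataFrame(
            {"a": base, "b": base, "c": rng.random(60) * 50, "d": rng.random(60) * 50}
        )
        coords, varexp = pca_samples(norm)
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-8)
        assert varexp.sum() <= 1.0 + 1e-9
        assert (np.diff(varexp.to_numpy()) <= 1e-12).all()


def test_run_de_returns_complete_table():
    rng = np.random.default_rng(20)
    G, n = 60, 4
    counts = pd.DataFrame(
        rng.integers(0, 400, size=(G, 2 * n)),
        index=[f"g{i}" for i in range(G)],
        columns=[f"c{i}" for i in range(n)] + [f"m{i}" for i in range(n)],
    )
    meta = pd.DataFrame(
        {"genotype": ["control"] * n + ["mutant"] * n, "stage": "two_cell"},
        index=counts.columns,
    )
    res = run_de(CountMatrix(counts, meta))
    assert set(res.columns) >= {"base_mean", "log2fc", "p", "padj", "de_class"}
    assert (res["padj"] >= res["p"] - 1e-12).all()
    assert res["de_class"].isin(["up", "down", "similar"]).all()
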