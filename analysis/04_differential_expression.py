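"""Gene-level differential expression on the single-embryo count matrix.

Applies the zero-count and top-60% gene filters, median-of-ratios size
factors, the NB Wald test with BH adjustment, and the up/down/similar
classification (|log2FC| >= 1 and padj < 0.05). Also writes the Spearman/Ward
sample tree (Newick) and PCA coordinates, and reports whether genotypes
separate cleanly — the single-embryo analogue of a clean mutant/control
clustering.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

from mztkit.containers import CountMatrix
from mztkit.de import (
    cluster_samples,
    filter_genes,
    linkage_to_newick,
    normalized_counts,
    pca_samples,
    run_de,
)


def main() -> None:
    matrix = CountMatrix.read(RESULTS / "counts.tsv", RESULTS / "sample_metadata.tsv")
    res = run_de(matrix)
    res.to_csv(RESULTS / "de_results.tsv", sep="\t", index_label="gene_id")
    counts = res["de_class"].value_counts()
    print(f"tested {len(res)} genes after filters "
          f"(of {len(matrix.gene_ids)} simulated): "
          f"{counts.get('up', 0)} up, {counts.get('down', 0)} down, "
          f"{counts.get('similar', 0)} similar")

    norm = normalized_counts(filter_genes(matrix).counts)
    Z, clusters = cluster_samples(norm)
    (RESULTS / "sample_tree.nwk").write_text(linkage_to_newick(Z, list(norm.columns)))
    genotype = matrix.metadata.loc[list(norm.columns), "genotype"]
    purity = (
        pd.crosstab(clusters, genotype).max(axis=1).sum() / len(norm.columns)
    )
    print(f"Spearman/Ward 2-cluster split purity vs genotype: {purity:.0%}")

    coords, varexp = pca_samples(norm)
    coords.to_csv(RESULTS / "pca_coordinates.tsv", sep="\t", index_label="sample_id")
    print(f"PC1 explains {varexp.iloc[0]:.0%} of variance "
          f"(PC2 {varexp.iloc[1]:.0%}); tree in results/sample_tree.nwk")


if __name__ == "__main__":
    main()
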