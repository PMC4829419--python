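"""Gene-level differential expression for single-embryo count matrices.

The workflow follows the classic count-based DE recipe:

1. drop genes with zero counts in every sample, then keep the top 60% of
   genes by mean size-factor-normalized count;
2. median-of-ratios size factors: s_j = median_i K_ij / (prod_j K_ij)^(1/m)
   over genes with a nonzero geometric mean;
3. a negative-binomial Wald test per gene (mutant vs control) with a
   method-of-moments dispersion shrunk halfway toward a 1/mu trend fit;
4. Benjamini-Hochberg adjustment and a three-way classification:
   up (log2FC >= +1 and padj < alpha), down (log2FC <= -1 and padj < alpha),
   similar otherwise.

Sample-level structure is summarized by Ward clustering on Spearman
correlation distance and by PCA of log2(normalized + 1) profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from mztkit.containers import CountMatrix

DE_CLASSES = ("up", "down", "similar")


@dataclass(frozen=True)
class DEConfig:
    alpha: float = 0.05
    log2fc_up: float = 1.0  # inclusive
    log2fc_down: float = -1.0  # inclusive
    top_expressed_fraction: float = 0.60

    def __post_init__(self) -> None:
        if not self.log2fc_down < 0 < self.log2fc_up:
            raise ValueError("need log2fc_down < 0 < log2fc_up")
        if not 0 < self.top_expressed_fraction <= 1:
            raise ValueError("top_expressed_fraction must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


# -- normalization ------------------------------------------------------------


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with all-positive counts."""
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in all samples")
    logs = np.log(arr[positive])
    geo = np.exp(logs.mean(axis=1, keepdims=True))
    factors = np.median(arr[positive] / geo, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def filter_genes(matrix: CountMatrix, config: DEConfig = DEConfig()) -> CountMatrix:
    """Remove all-zero genes, then keep the ceil(fraction * G) top-expressed genes.

    "Top expressed" ranks genes by mean size-factor-normalized count; ties are
    broken by gene id (ascending), so the filter is deterministic.
    """
    counts = matrix.counts
    nonzero = counts.loc[(counts > 0).any(axis=1)]
    if nonzero.empty:
        raise ValueError("all genes have zero counts")
    norm = normalized_counts(nonzero)
    n_keep = math.ceil(config.top_expressed_fraction * len(nonzero))
    ranking = (
        norm.mean(axis=1)
        .rename("mean_norm")
        .rename_axis("gene_id")
        .reset_index()
        .sort_values(["mean_norm", "gene_id"], ascending=[False, True], kind="mergesort")
    )
    keep = sorted(ranking["gene_id"].iloc[:n_keep])
    return matrix.subset_genes(keep)


# -- negative-binomial testing ------------------------------------------------


def _trend_dispersion(base_mean: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu by least squares (coefficients clipped >= 0)."""
    ok = alpha_mom > 0
    if ok.sum() < 2:
        return np.full_like(base_mean, max(alpha_mom.max(initial=0.0), 1e-8))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha_mom[ok], rcond=None)
    coef = np.clip(coef, 0.0, None)
    trend = coef[0] + coef[1] / base_mean
    return np.clip(trend, 1e-8, None)


def nb_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    design: pd.Series,
) -> pd.DataFrame:
    """Per-gene NB Wald test of mutant vs control.

    ``design`` maps sample id -> genotype. The log2 fold change is
    log2((mean normalized mutant + 0.5) / (mean normalized control + 0.5)).
    The Wald statistic uses a delta-method standard error with an NB variance
    mu/s + alpha*mu^2 per sample and a gene-wise dispersion that averages the
    method-of-moments estimate with a 1/mu trend fit (50/50). P-values are
    two-sided from a t reference with n1 + n2 - 2 degrees of freedom, which
    accounts for the moment-estimated dispersion at single-embryo sample
    sizes (calibration is exercised by the type-I simulation in the tests).
    """
    design = design.reindex(counts.columns)
    ctrl = design.index[design == "control"]
    mut = design.index[design == "mutant"]
    if len(ctrl) < 2 or len(mut) < 2:
        raise ValueError("need >=2 samples per genotype")

    norm = counts / factors
    mu_c = norm[ctrl].mean(axis=1).to_numpy()
    mu_m = norm[mut].mean(axis=1).to_numpy()
    base_mean = norm.mean(axis=1).to_numpy()

    # pooled within-group variance of normalized counts (moment estimator)
    var_w = (
        norm[ctrl].var(axis=1, ddof=1) * (len(ctrl) - 1)
        + norm[mut].var(axis=1, ddof=1) * (len(mut) - 1)
    ).to_numpy() / (len(ctrl) + len(mut) - 2)
    # normalized counts have variance mu/s + alpha*mu^2; subtract shot noise
    inv_s = float((1.0 / factors).mean())
    mu_bar = (mu_c * len(ctrl) + mu_m * len(mut)) / (len(ctrl) + len(mut))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(
            mu_bar > 0, (var_w - mu_bar * inv_s) / np.maximum(mu_bar, 1e-12) ** 2, 0.0
        )
    alpha_mom = np.clip(alpha_mom, 0.0, 10.0)
    alpha_trend = _trend_dispersion(np.maximum(base_mean, 1e-8), alpha_mom)
    alpha_use = np.clip(0.5 * alpha_mom + 0.5 * alpha_trend, 1e-8, 10.0)

    log2fc = np.log2((mu_m + 0.5) / (mu_c + 0.5))

    inv_s_c = float((1.0 / factors[ctrl]).mean())
    inv_s_m = float((1.0 / factors[mut]).mean())
    var_mean_c = (mu_c * inv_s_c + alpha_use * mu_c**2) / len(ctrl)
    var_mean_m = (mu_m * inv_s_m + alpha_use * mu_m**2) / len(mut)
    ln2_sq = np.log(2.0) ** 2
    se = np.sqrt(
        var_mean_c / ((mu_c + 0.5) ** 2 * ln2_sq)
        + var_mean_m / ((mu_m + 0.5) ** 2 * ln2_sq)
    )
    df = len(ctrl) + len(mut) - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(wald), df=df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "stat": wald,
            "p": p,
        },
        index=counts.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_de(
    log2fc: np.ndarray, padj: np.ndarray, config: DEConfig = DEConfig()
) -> np.ndarray:
    """Three-way up/down/similar classification (thresholds inclusive, FDR-gated)."""
    log2fc = np.asarray(log2fc, dtype=float)
    padj = np.asarray(padj, dtype=float)
    if not (np.isfinite(log2fc).all() and np.isfinite(padj).all()):
        raise ValueError("non-finite inputs")
    out = np.full(log2fc.shape, "similar", dtype=object)
    sig = padj < config.alpha
    out[sig & (log2fc >= config.log2fc_up)] = "up"
    out[sig & (log2fc <= config.log2fc_down)] = "down"
    return out


def run_de(matrix: CountMatrix, config: DEConfig = DEConfig()) -> pd.DataFrame:
    """Full DE stage: gene filters, size factors, NB test, BH, classification."""
    filtered = filter_genes(matrix, config)
    factors = size_factors(filtered.counts)
    design = filtered.metadata.loc[list(filtered.counts.columns), "genotype"]
    res = nb_test(filtered.counts, factors, design)
    res["padj"] = bh_adjust(res["p"].to_numpy())
    res["de_class"] = classify_de(res["log2fc"].to_numpy(), res["padj"].to_numpy(), config)
    return res


# -- sample-level structure ---------------------------------------------------


def spearman_distance(norm_counts: pd.DataFrame) -> pd.DataFrame:
    """1 - Spearman rho between sample expression profiles."""
    rho = stats.spearmanr(norm_counts.to_numpy()).statistic
    rho = np.atleast_2d(rho)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0
    return pd.DataFrame(d, index=norm_counts.columns, columns=norm_counts.columns)


def cluster_samples(norm_counts: pd.DataFrame):
    """Ward linkage over Spearman correlation distance; returns (Z, 2-cluster labels).

    Profiles are log2(normalized + 1)-transformed first (rank-based distance
    makes this a no-op for the distances, kept for symmetry with PCA).
    """
    if norm_counts.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    logn = np.log2(norm_counts + 1.0)
    dist = spearman_distance(logn)
    condensed = squareform(dist.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method="ward")
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return Z, pd.Series(labels, index=norm_counts.columns, name="cluster")


def linkage_to_newick(Z: np.ndarray, leaf_names: list) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def render(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        left, right = render(node.left), render(node.right)
        dl = max(node.dist - node.left.dist, 0.0)
        dr = max(node.dist - node.right.dist, 0.0)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return render(tree) + ";"


def pca_samples(norm_counts: pd.DataFrame, n_components: int | None = None):
    """PCA of log2(normalized + 1) sample profiles, genes centered.

    Returns (coordinates DataFrame samples x PCs, variance-explained Series).
    """
    from sklearn.decomposition import PCA

    if norm_counts.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    X = np.log2(norm_counts + 1.0).to_numpy().T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    cols = [f"PC{i+1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=norm_counts.columns, columns=cols),
        pd.Series(pca.explained_variance_ratio_, index=cols, name="variance_explained"),
    )


def normalize_to_housekeeping(expression: pd.DataFrame, housekeeping_ids) -> pd.DataFrame:
    """Divide each sample by the geometric mean of its housekeeping genes."""
    hk = expression.loc[list(housekeeping_ids)]
    if (hk.to_numpy() <= 0).any():
        raise ValueError("housekeeping values must be > 0")
    geomean = np.exp(np.log(hk).mean(axis=0))
    return expression / geomean
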