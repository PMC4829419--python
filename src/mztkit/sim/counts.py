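"""Simulated single-embryo count matrices with wave structure.

Counts are negative-binomial with variance mu + alpha*mu^2 (the standard
RNA-seq parameterization). A planted genotype effect is applied to a fraction
of genes per wave category: categories whose transcripts predate major ZGA
(maternal, minor ZGA, 1C transient) go UP in the mutant, categories activated
at or after the two-cell stage (major ZGA, 2C transient, MGA) go DOWN —
the direction of the transcriptome phenotype the pipeline is built to detect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mztkit.catalogue import (
    EARLY_CATEGORIES,
    LATE_CATEGORIES,
    WAVE_CATEGORIES,
    WaveCatalogue,
)
from mztkit.containers import CountMatrix


@dataclass(frozen=True)
class CountSimConfig:
    """Parameters of the embryo-count simulation.

    Defaults mirror the study design the generator emulates: 8 single embryos
    per genotype group, moderate biological dispersion (alpha = 0.1), planted
    two-fold-squared (|log2FC| = 2) effects on half of each category.
    """

    n_genes_per_category: int = 200
    n_samples_per_group: int = 8
    nb_mean_range: tuple = (20.0, 500.0)
    nb_dispersion: float = 0.1
    effect_log2fc_up: float = 2.0
    effect_log2fc_down: float = -2.0
    affected_fraction: float = 0.5
    stage: str = "two_cell"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes_per_category < 1:
            raise ValueError("n_genes_per_category must be >= 1")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must be in [0, 1]")
        lo, hi = self.nb_mean_range
        if not (0 < lo <= hi):
            raise ValueError("nb_mean_range must be positive and ordered")


def make_wave_catalogue(config: CountSimConfig) -> WaveCatalogue:
    """Build a catalogue with ``n_genes_per_category`` genes per category.

    Gene ids encode their category (``g_maternal_0001`` ...), so planted
    membership is recoverable by eye; the mapping is deterministic.
    """
    entries = {}
    for cat in WAVE_CATEGORIES:
        for i in range(config.n_genes_per_category):
            entries[f"g_{cat}_{i:04d}"] = cat
    return WaveCatalogue(entries)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    # numpy's NB is (n, p) with mean n(1-p)/p; n = 1/alpha, p = 1/(1+alpha*mu)
    n = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mean)
    return rng.negative_binomial(n, p)


def simulate_embryo_counts(
    catalogue: WaveCatalogue, config: CountSimConfig
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw NB counts for control and mutant embryos over a wave catalogue.

    Returns the count matrix and a ground-truth table with each gene's
    category, baseline mean, planted log2 fold change (0 when unaffected)
    and the resulting mutant mean.
    """
    if len(catalogue) == 0:
        raise ValueError("empty catalogue")
    rng = np.random.default_rng(config.seed)
    genes = sorted(catalogue.entries)
    cats = np.array([catalogue.category_of(g) for g in genes])
    lo, hi = config.nb_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))

    planted = np.zeros(len(genes))
    for cat in WAVE_CATEGORIES:
        idx = np.flatnonzero(cats == cat)
        n_aff = int(round(config.affected_fraction * len(idx)))
        chosen = rng.choice(idx, size=n_aff, replace=False)
        if cat in EARLY_CATEGORIES:
            planted[chosen] = config.effect_log2fc_up
        else:
            assert cat in LATE_CATEGORIES
            planted[chosen] = config.effect_log2fc_down

    mutant_mean = base_mean * 2.0**planted
    n = config.n_samples_per_group
    ctrl = _nb_draw(rng, base_mean[:, None] * np.ones((1, n)), config.nb_dispersion)
    mut = _nb_draw(rng, mutant_mean[:, None] * np.ones((1, n)), config.nb_dispersion)

    sample_ids = [f"ctrl_{i+1}" for i in range(n)] + [f"mut_{i+1}" for i in range(n)]
    counts = pd.DataFrame(
        np.hstack([ctrl, mut]), index=pd.Index(genes, name="gene_id"), columns=sample_ids
    )
    metadata = pd.DataFrame(
        {
            "genotype": ["control"] * n + ["mutant"] * n,
            "stage": config.stage,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = pd.DataFrame(
        {
            "category": cats,
            "base_mean": base_mean,
            "planted_log2fc": planted,
            "mutant_mean": mutant_mean,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return CountMatrix(counts, metadata), truth
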