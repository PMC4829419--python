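"""Generate the demo study inputs: wave-structured embryo counts and a repeat genome.

Writes the single-embryo count matrix (8 control + 8 mutant two-cell embryos,
100 genes per wave category, planted |log2FC| = 2 effects on half of each
category), its ground-truth table, the wave catalogue, and the repeat
annotation (BED + family->class TSV) to results/. The 50 kb genome sequence
itself goes to scratch/ (regenerable from the seed).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DEMO_SEED, RESULTS, SCRATCH, counts_config, genome_config

from mztkit.sim import make_wave_catalogue, simulate_embryo_counts, simulate_repeat_genome


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    (SCRATCH / "raw").mkdir(parents=True, exist_ok=True)

    cfg = counts_config()
    catalogue = make_wave_catalogue(cfg)
    matrix, truth = simulate_embryo_counts(catalogue, cfg)
    matrix.write(RESULTS / "counts.tsv", RESULTS / "sample_metadata.tsv")
    catalogue.write(RESULTS / "wave_catalogue.tsv")
    truth.to_csv(RESULTS / "counts_truth.tsv", sep="\t")
    n_aff = int((truth["planted_log2fc"] != 0).sum())
    print(
        f"counts: {len(matrix.gene_ids)} genes x {len(matrix.sample_ids)} embryos, "
        f"{n_aff} genes carry a planted effect (log2FC +{cfg.effect_log2fc_up} on "
        f"maternal/minor-ZGA/1C-transient, {cfg.effect_log2fc_down} on the rest)"
    )

    genome, annotation, rrna = simulate_repeat_genome(genome_config())
    annotation.write(RESULTS / "repeats.bed", RESULTS / "repeat_classes.tsv")
    with open(SCRATCH / "raw" / "genome.fa", "w") as fh:
        fh.write(">genome\n")
        for i in range(0, len(genome), 80):
            fh.write(genome[i : i + 80] + "\n")
        for name, seq in rrna.items():
            fh.write(f">{name}\n{seq}\n")
    print(
        f"repeat genome: {len(genome):,} bp, {len(annotation)} repeat copies in "
        f"{len(annotation.families)} families, {len(rrna)} rRNA decoys "
        f"(sequence in scratch/raw/genome.fa)"
    )


if __name__ == "__main__":
    main()
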