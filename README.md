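# mztkit

Desk-scale re-implementation of the computational pipeline behind a
single-embryo study of the mouse maternal-to-zygotic transition (MZT): what
happens to the transcriptome, to transposable-element expression, and to
nuclear fluorescence patterns when a maternal chromatin factor is missing at
the two-cell stage. The package is for computational biologists who want the
study's bespoke procedures — not its raw data — as tested, reusable code
driven by simulations with planted ground truth.

Three analysis strands, each a package module with a matching numbered
driver script:

1. **Repeat quantification from multi-mapped reads** (`readqc`, `mapping`,
   `repeats`). Reads are QC-filtered (Phred, N-content, AT-content,
   homopolymer rules), screened against rRNA decoys, and mapped to *all*
   zero-mismatch genomic locations (up to 10,000). A read counts toward a
   repeat family only if every alignment falls inside annotated repeats and
   the majority family exceeds 95% of hits — the family-concordance filter.
   Family counts are normalized by total repeat-assigned reads and tested
   per family (Welch t on log fractions, BH-adjusted).
2. **Single-embryo differential expression and ZGA waves** (`de`, `waves`).
   Median-of-ratios size factors s_j = median_i K_ij/(Π_j K_ij)^{1/m}, an NB
   Wald test (variance μ + αμ², trend-shrunk dispersion), BH adjustment, and
   the three-way call: up iff log2FC ≥ 1 and padj < 0.05, down iff
   log2FC ≤ −1 and padj < 0.05, else similar. Calls are cross-tabulated
   against six-wave gene catalogues (maternal, minor ZGA, 1C transient,
   major ZGA, 2C transient, MGA), with Spearman/Ward clustering and PCA of
   sample profiles.
3. **Nuclear-image quantification** (`images`). Integrated intensity (in-mask
   sum / voxel count), group fold changes with Welch t-tests gated by
   Shapiro–Wilk normality checks, gray-level co-occurrence texture (Haralick
   entropy −Σ p log₂ p and friends) of FISH-like foci, and chi-square tests
   of categorical phenotype proportions.

Everything is fed by `mztkit.sim`, which generates wave-structured embryo
count matrices, repeat genomes with near-identical interspersed copies (the
multi-mapping substrate) plus rRNA decoys, FASTQ reads with injectable QC
failures, and punctate nucleus images with planted intensity ratios.

## Worked example

Running the numbered drivers in order (all regenerate their inputs
deterministically from one seed):

```
$ python analysis/01_simulate_inputs.py
counts: 600 genes x 16 embryos, 300 genes carry a planted effect (log2FC +2.0 on
maternal/minor-ZGA/1C-transient, -2.0 on the rest)
repeat genome: 50,000 bp, 20 repeat copies in 5 families, 4 rRNA decoys ...

$ python analysis/03_repeat_quantification.py
planted 2.0-fold increase on LINE_fam00; recovered normalized-fraction fold 1.96 ...
LINE_fam00 significant: True (padj = 2.20e-09); 3 of 5 families called

$ python analysis/04_differential_expression.py
tested 360 genes after filters (of 600 simulated): 133 up, 59 down, 168 similar
Spearman/Ward 2-cluster split purity vs genotype: 100%
PC1 explains 70% of variance (PC2 3%); tree in results/sample_tree.nwk

$ python analysis/05_wave_overlap.py
...
published worked example (upregulated percent of category):
  maternal: 37% (coverage 96.8%)
  minor_ZGA: 39% (coverage 97.1%)
  1C_transient: 38% (coverage 98.9%)

$ python analysis/06_image_quantification.py
planted intensity ratio 2.2; recovered 2.200 from 50 pairs (t-test p = 3.54e-253)
GLCM entropy mutant vs control: t = -10.44, p = 1.90e-17 [normality flag raised]
```

Reading the numbers: the repeat stage recovers the planted two-fold LINE
increase as 1.96 on normalized fractions (normalization by total repeat reads
is compositional, so the expected recovered ratio is slightly below 2; see
`docs/methods.md`), and flags the family significant. The DE stage finds the
planted up/down structure, splits genotypes perfectly by Spearman/Ward
clustering, and — run on the published cross-tabulation counts — reproduces
the printed per-category percentages exactly. The image stage recovers a
planted 2.2-fold nuclear-intensity difference to three digits and separates
the two groups' focus textures by co-occurrence entropy.

The full pipeline can also be run as one reproducible job with a YAML-style
config via `mztkit.pipeline.run_pipeline`, which writes every stage's TSV
outputs plus a JSON report recording all seeds, thresholds, and conservation
tallies.

## Layout

```
src/mztkit/        library: sim/, readqc, mapping, repeats, de, waves,
                   images, pipeline, containers, catalogue, io
analysis/          numbered narrative drivers (01 simulate ... 06 images)
tests/             pytest suite, including end-to-end recovery tests
scripts/           acceptance.py (headline quantification as JSON)
docs/methods.md    model, assumptions, parameter choices, limitations
results/           tables written by the analysis scripts
```
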