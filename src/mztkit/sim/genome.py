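"""Synthetic repeat genomes: near-identical interspersed copies + rRNA decoys.

Each repeat family has a random consensus sequence and several copies placed
at non-overlapping genomic positions; copies differ from the consensus by at
most (1 - identity) * copy_length substitutions, so a short read drawn from
one copy typically matches several — the multi-mapping regime the
family-concordance filter is designed for. Ribosomal-RNA decoy sequences are
generated alongside for the rRNA pre-filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mztkit.repeats import REPEAT_CLASSES, RepeatAnnotation

BASES = np.array(list("ACGT"))

DEFAULT_RRNA_REFS = (
    ("rRNA_18S", 400),
    ("rRNA_28S", 600),
    ("rRNA_5.8S", 157),
    ("rRNA_5S", 121),
)


@dataclass(frozen=True)
class RepeatGenomeConfig:
    n_families: int = 5
    copies_per_family: int = 4
    copy_length: int = 300
    intra_family_identity: float = 0.98
    genome_length: int = 100_000
    rrna_refs: tuple = DEFAULT_RRNA_REFS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.9 < self.intra_family_identity <= 1.0:
            raise ValueError("intra_family_identity must be in (0.9, 1.0]")
        total = self.n_families * self.copies_per_family * self.copy_length
        if total > self.genome_length:
            raise ValueError("repeat copies cannot fit in the genome without overlap")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    if n_sub == 0:
        return seq
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=n_sub, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(len(choices))]
    return "".join(arr)


def _place_intervals(
    rng: np.random.Generator, n: int, length: int, genome_length: int
) -> list:
    """Sample n non-overlapping [start, start+length) intervals.

    Distributes the slack (genome minus total copy length) uniformly among
    the gaps, so placement never fails for feasible geometries.
    """
    slack = genome_length - n * length
    vals = np.sort(rng.integers(0, slack + 1, size=n))
    starts = vals + np.arange(n) * length
    return [(int(s), int(s) + length) for s in starts]


def simulate_repeat_genome(config: RepeatGenomeConfig):
    """Generate (genome_sequence, RepeatAnnotation, rrna_references).

    The annotation is 0-based half-open with non-overlapping intervals; family
    classes cycle through LINE, SINE, LTR, other.
    """
    rng = np.random.default_rng(config.seed)
    genome = list(_random_seq(rng, config.genome_length))

    n_total = config.n_families * config.copies_per_family
    intervals = _place_intervals(
        rng, n_total, config.copy_length, config.genome_length
    )
    max_sub = int((1.0 - config.intra_family_identity) * config.copy_length)

    rows = []
    # interleave families along the genome rather than blocking them together
    order = rng.permutation(n_total)
    intervals = [intervals[i] for i in order]
    it = iter(intervals)
    for fam_i in range(config.n_families):
        cls = REPEAT_CLASSES[fam_i % len(REPEAT_CLASSES)]
        family = f"{cls}_fam{fam_i:02d}"
        consensus = _random_seq(rng, config.copy_length)
        for _ in range(config.copies_per_family):
            start, end = next(it)
            n_sub = int(rng.integers(0, max_sub + 1))
            copy_seq = _mutate(rng, consensus, n_sub)
            genome[start:end] = list(copy_seq)
            rows.append(("genome", start, end, family, cls))

    annotation = RepeatAnnotation(
        pd.DataFrame(rows, columns=["reference", "start", "end", "family", "repeat_class"])
    )
    rrna = {name: _random_seq(rng, length) for name, length in config.rrna_refs}
    return "".join(genome), annotation, rrna
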