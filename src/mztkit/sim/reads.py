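"""Simulated FASTQ reads from repeat transcripts, with injected QC failures.

Each annotated repeat copy (and each rRNA decoy, when given a positive
abundance) is treated as one transcript. Exactly ``n_reads`` reads are drawn;
per-transcript depths are multinomial — i.e. Poisson conditioned on the fixed
total — so abundance ratios are preserved in expectation. Reads are
error-free at the alignment level: mismatches against other copies arise only
from inter-copy divergence. Optional QC-noise injection *modifies* (never
drops) a configurable fraction of reads so the QC stage has something to
discard: low-quality runs, N bases, or poly-A tails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mztkit.mapping import revcomp
from mztkit.readqc import Read
from mztkit.repeats import RepeatAnnotation

HIGH_QUALITY = 40
LOW_QUALITY = 2


@dataclass(frozen=True)
class QCNoiseParams:
    """Rates of injected QC-failure modes (at most one per read)."""

    low_quality_rate: float = 0.0
    n_rate: float = 0.0
    polyat_rate: float = 0.0

    def __post_init__(self) -> None:
        rates = (self.low_quality_rate, self.n_rate, self.polyat_rate)
        if any(r < 0 for r in rates) or sum(rates) > 1.0:
            raise ValueError("noise rates must be >= 0 and sum to <= 1")


def _inject_low_quality(rng, seq: str, qual: np.ndarray) -> tuple[str, np.ndarray]:
    n_low = len(seq) // 2 + 1  # strictly more than 50% of bases below Phred 5
    pos = rng.choice(len(seq), size=n_low, replace=False)
    qual = qual.copy()
    qual[pos] = LOW_QUALITY
    return seq, qual


def _inject_n(rng, seq: str, qual: np.ndarray) -> tuple[str, np.ndarray]:
    n_n = int(0.05 * len(seq)) + 1  # strictly more than 5% N
    pos = rng.choice(len(seq), size=n_n, replace=False)
    arr = list(seq)
    for p in pos:
        arr[p] = "N"
    return "".join(arr), qual


def _inject_polyat(rng, seq: str, qual: np.ndarray) -> tuple[str, np.ndarray]:
    run = max(15, math.ceil(0.30 * len(seq)))
    base = "A" if rng.random() < 0.5 else "T"
    return seq[:-run] + base * run, qual


_NOISE_MODES = (
    ("low_quality", _inject_low_quality),
    ("n_bases", _inject_n),
    ("polyat", _inject_polyat),
)


def simulate_reads(
    genome: str,
    annotation: RepeatAnnotation,
    family_abundances: dict,
    read_length: int = 49,
    n_reads: int = 10_000,
    qc_noise: QCNoiseParams = QCNoiseParams(),
    rrna_references: dict | None = None,
    rrna_abundance: float = 0.0,
    seed: int = 0,
):
    """Draw reads from repeat transcripts proportional to family abundance.

    ``family_abundances`` maps family -> non-negative weight (split equally
    across the family's copies); ``rrna_abundance`` is split across the decoy
    references. Returns (reads, truth) where truth records each read's source
    transcript, family, strand and injected noise mode.
    """
    rng = np.random.default_rng(seed)
    if any(a < 0 for a in family_abundances.values()) or (
        sum(family_abundances.values()) + rrna_abundance
    ) <= 0:
        raise ValueError("abundances must be >= 0 and not all zero")

    # transcripts: (name, family, sequence)
    transcripts: list = []
    weights: list = []
    fam_copies: dict = {}
    for _, row in annotation.intervals.iterrows():
        fam_copies.setdefault(row["family"], []).append(
            genome[row["start"] : row["end"]]
        )
    for fam, abundance in family_abundances.items():
        if fam not in fam_copies:
            raise ValueError(f"family {fam!r} not in annotation")
        copies = fam_copies[fam]
        for i, seq in enumerate(copies):
            transcripts.append((f"{fam}/copy{i}", fam, seq))
            weights.append(abundance / len(copies))
    if rrna_abundance > 0:
        if not rrna_references:
            raise ValueError("rrna_abundance > 0 but no rRNA references given")
        for name, seq in rrna_references.items():
            transcripts.append((name, "rRNA", seq))
            weights.append(rrna_abundance / len(rrna_references))

    for name, _, seq in transcripts:
        if read_length > len(seq):
            raise ValueError(f"read_length {read_length} > transcript {name} length")

    probs = np.asarray(weights, dtype=float)
    probs = probs / probs.sum()
    depth = rng.multinomial(n_reads, probs)

    noise_names = [m for m, _ in _NOISE_MODES]
    noise_probs = [qc_noise.low_quality_rate, qc_noise.n_rate, qc_noise.polyat_rate]
    noise_probs.append(1.0 - sum(noise_probs))
    noise_names.append("none")

    reads: list = []
    rows: list = []
    read_i = 0
    for (name, fam, seq), d in zip(transcripts, depth):
        starts = rng.integers(0, len(seq) - read_length + 1, size=d)
        strands = np.where(rng.random(d) < 0.5, "+", "-")
        for start, strand in zip(starts, strands):
            frag = seq[start : start + read_length]
            if strand == "-":
                frag = revcomp(frag)
            qual = np.full(read_length, HIGH_QUALITY)
            mode = noise_names[rng.choice(len(noise_names), p=noise_probs)]
            for mode_name, inject in _NOISE_MODES:
                if mode == mode_name:
                    frag, qual = inject(rng, frag, qual)
            reads.append(Read(f"read_{read_i:06d}", frag, tuple(int(q) for q in qual)))
            rows.append((f"read_{read_i:06d}", name, fam, strand, mode))
            read_i += 1

    truth = pd.DataFrame(
        rows, columns=["read_id", "transcript", "family", "strand", "noise"]
    ).set_index("read_id")
    return reads, truth
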