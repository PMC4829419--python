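"""Read-level quality-control filters.

A read is discarded if ANY of the following fires (checked in this order,
the reported reason is the first that fires):

1. low_quality — more than 50% of bases below Phred 5 (strict);
2. n_bases    — more than 5% N bases (strict);
3. at_rich    — A+T fraction above 80% (strict; Ns excluded from both
   numerator and denominator);
4. homopolymer — a continuous run of a single base A or T of length at
   least max(15, ceil(0.30 * read length)). The two printed thresholds
   (15 bases, 30%) coincide at 49-bp reads; the max reconciles them for
   other read lengths.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

QC_REASONS = ("low_quality", "n_bases", "at_rich", "homopolymer", "pass")

_RUN_RE = re.compile(r"A+|T+")


@dataclass(frozen=True)
class Read:
    """A sequencing read: id, bases, per-base Phred scores."""

    id: str
    sequence: str
    quality: tuple

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"{self.id}: |sequence| != |quality|")

    @classmethod
    def from_phred33(cls, read_id: str, sequence: str, quality_string: str) -> "Read":
        return cls(read_id, sequence, tuple(ord(c) - 33 for c in quality_string))

    def quality_string(self) -> str:
        return "".join(chr(q + 33) for q in self.quality)


@dataclass(frozen=True)
class QCConfig:
    low_quality_phred_threshold: int = 5
    max_low_quality_fraction: float = 0.50
    max_n_fraction: float = 0.05
    max_at_fraction: float = 0.80
    min_homopolymer_run: int = 15
    homopolymer_fraction: float = 0.30

    def __post_init__(self) -> None:
        for name in ("max_low_quality_fraction", "max_n_fraction", "max_at_fraction",
                     "homopolymer_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def qc_filter(read: Read, config: QCConfig = QCConfig()) -> tuple[bool, str]:
    """Return (keep, reason); reason is the first firing criterion or 'pass'."""
    length = len(read.sequence)
    if length == 0:
        raise ValueError(f"{read.id}: empty sequence")
    seq = read.sequence.upper()

    qual = np.asarray(read.quality)
    if (qual < config.low_quality_phred_threshold).sum() / length > config.max_low_quality_fraction:
        return False, "low_quality"

    n_count = seq.count("N")
    if n_count / length > config.max_n_fraction:
        return False, "n_bases"

    at_count = seq.count("A") + seq.count("T")
    denom = length - n_count
    if denom > 0 and at_count / denom > config.max_at_fraction:
        return False, "at_rich"

    run_needed = max(config.min_homopolymer_run,
                     math.ceil(config.homopolymer_fraction * length))
    for m in _RUN_RE.finditer(seq):
        if m.end() - m.start() >= run_needed:
            return False, "homopolymer"

    return True, "pass"


def qc_filter_reads(reads, config: QCConfig = QCConfig()):
    """Filter an iterable of reads; returns (survivors, tallies by reason)."""
    tallies = {r: 0 for r in QC_REASONS}
    kept = []
    for read in reads:
        keep, reason = qc_filter(read, config)
        tallies[reason] += 1
        if keep:
            kept.append(read)
    return kept, tallies
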