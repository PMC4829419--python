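"""Best-hit multi-mapping against small synthetic genomes.

The mapper reports, for each read, ALL zero-mismatch locations on both
strands, up to a configurable cap (default 10,000 locations). Reads whose
hit count exceeds the cap, or with no hit at all, are dropped and tallied.
A pre-filter removes reads with a unique best alignment to a ribosomal-RNA
reference (at most 2 mismatches in the seed region — the first 28 bases).

Alignment records round-trip through minimal SAM (MAPQ 0 for multi-hit
reads, NM tag for mismatches).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from mztkit.readqc import Read

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Hit:
    """One alignment location (0-based half-open, strand '+'/'-')."""

    reference: str
    start: int
    end: int
    strand: str
    n_mismatches: int = 0


@dataclass(frozen=True)
class AlignmentRecord:
    """One read's set of equally-best hits (all share the minimal mismatch count)."""

    read_id: str
    hits: tuple

    def __post_init__(self) -> None:
        if not self.hits:
            raise ValueError(f"{self.read_id}: record with no hits")
        if len({h.n_mismatches for h in self.hits}) != 1:
            raise ValueError(f"{self.read_id}: hits with unequal mismatch counts")


@dataclass(frozen=True)
class MapConfig:
    max_locations: int = 10_000
    max_mismatches_repeat: int = 0
    rrna_seed_mismatch_limit: int = 2  # "less than 3 mismatches in the seed"
    rrna_seed_length: int = 28  # Bowtie default seed
    rrna_references: dict = None

    def __post_init__(self) -> None:
        if self.max_locations < 1:
            raise ValueError("max_locations must be >= 1")
        if self.max_mismatches_repeat < 0 or self.rrna_seed_mismatch_limit < 0:
            raise ValueError("mismatch limits must be >= 0")


def _as_ref_dict(genome) -> dict:
    return {"genome": genome} if isinstance(genome, str) else dict(genome)


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _scan_mismatches(ref_arr: np.ndarray, read_arr: np.ndarray) -> np.ndarray:
    """Mismatch count of the read against every window of the reference."""
    L = len(read_arr)
    if len(ref_arr) < L:
        return np.zeros(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
    return (windows != read_arr).sum(axis=1)


class _ExactIndex:
    """Exact k-mer index of a reference set, one k per read length."""

    def __init__(self, references: dict):
        self.references = {name: seq.upper() for name, seq in references.items()}
        self._indexes: dict = {}

    def positions(self, seq: str) -> list:
        k = len(seq)
        if k not in self._indexes:
            idx: dict = {}
            for name, ref in self.references.items():
                for i in range(len(ref) - k + 1):
                    idx.setdefault(ref[i : i + k], []).append((name, i))
            self._indexes[k] = idx
        return self._indexes[k].get(seq.upper(), [])


def map_multi(reads, genome, config: MapConfig = MapConfig()):
    """Map reads to all best (zero-mismatch) locations on both strands.

    Returns (records, tallies) where tallies counts 'mapped', 'unmapped'
    and 'over_cap' reads. Records are sorted by read id, so output is
    independent of input order.
    """
    if config.max_mismatches_repeat != 0:
        raise NotImplementedError("only zero-mismatch repeat mapping is supported")
    refs = _as_ref_dict(genome)
    index = _ExactIndex(refs)
    tallies = {"mapped": 0, "unmapped": 0, "over_cap": 0}
    records = []
    for read in reads:
        L = len(read.sequence)
        for name, ref in refs.items():
            if len(ref) < L:
                raise ValueError(f"reference {name} shorter than read {read.id}")
        hits = [
            Hit(name, pos, pos + L, "+", 0)
            for name, pos in index.positions(read.sequence)
        ]
        rc = revcomp(read.sequence)
        hits += [Hit(name, pos, pos + L, "-", 0) for name, pos in index.positions(rc)]
        if not hits:
            tallies["unmapped"] += 1
        elif len(hits) > config.max_locations:
            tallies["over_cap"] += 1
        else:
            tallies["mapped"] += 1
            hits.sort(key=lambda h: (h.reference, h.start, h.strand))
            records.append(AlignmentRecord(read.id, tuple(hits)))
    records.sort(key=lambda r: r.read_id)
    return records, tallies


_BIG = np.iinfo(np.int32).max


def filter_rrna(reads, config: MapConfig, chunk_size: int = 512):
    """Drop reads with a UNIQUE best rRNA alignment within the seed limit.

    A candidate alignment has at most ``rrna_seed_mismatch_limit`` mismatches
    in the read's first ``rrna_seed_length`` bases; among candidates (both
    strands, all decoys) the best has minimal total mismatches. The read is
    removed iff exactly one alignment attains that minimum — a read matching
    two decoys equally well is kept, per the unique-best rule.

    Returns (survivors, n_discarded). Reads are compared to every reference
    window in vectorized chunks.
    """
    if not config.rrna_references:
        raise ValueError("rRNA reference set is empty")
    reads = list(reads)
    ref_arrays = [_seq_array(seq) for seq in config.rrna_references.values()]
    discard = np.zeros(len(reads), dtype=bool)

    by_length: dict = {}
    for i, read in enumerate(reads):
        by_length.setdefault(len(read.sequence), []).append(i)

    for L, idxs in by_length.items():
        seed_len = min(config.rrna_seed_length, L)
        fwd = np.stack([_seq_array(reads[i].sequence) for i in idxs])
        rev = np.stack([_seq_array(revcomp(reads[i].sequence)) for i in idxs])
        best = np.full(len(idxs), _BIG, dtype=np.int64)
        n_best = np.zeros(len(idxs), dtype=np.int64)
        for ref_arr in ref_arrays:
            if len(ref_arr) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
            for oriented in (fwd, rev):
                for lo in range(0, len(idxs), chunk_size):
                    chunk = oriented[lo : lo + chunk_size]
                    diff = chunk[:, None, :] != windows[None, :, :]
                    seed_mm = diff[:, :, :seed_len].sum(axis=2)
                    total_mm = diff.sum(axis=2)
                    masked = np.where(
                        seed_mm <= config.rrna_seed_mismatch_limit, total_mm, _BIG
                    )
                    row_min = masked.min(axis=1)
                    row_cnt = (masked == row_min[:, None]).sum(axis=1)
                    sl = slice(lo, lo + len(chunk))
                    better = row_min < best[sl]
                    equal = (row_min == best[sl]) & (row_min < _BIG)
                    best[sl] = np.where(better, row_min, best[sl])
                    n_best[sl] = np.where(better, row_cnt, n_best[sl])
                    n_best[sl] += np.where(equal, row_cnt, 0)
        discard[np.asarray(idxs)] = (best < _BIG) & (n_best == 1)

    kept = [r for r, d in zip(reads, discard) if not d]
    return kept, int(discard.sum())


# -- minimal SAM round trip ---------------------------------------------------


def write_sam(records, reference_lengths: dict, path: str | Path) -> None:
    """Write alignment records as minimal SAM (POS 1-based, MAPQ 0 for multi-hits)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in reference_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rec in records:
            mapq = 0 if len(rec.hits) > 1 else 60
            for i, hit in enumerate(rec.hits):
                flag = 0 if hit.strand == "+" else 16
                if i > 0:
                    flag |= 256  # secondary
                length = hit.end - hit.start
                fh.write(
                    f"{rec.read_id}\t{flag}\t{hit.reference}\t{hit.start + 1}\t"
                    f"{mapq}\t{length}M\t*\t0\t0\t*\t*\tNM:i:{hit.n_mismatches}\n"
                )


def read_sam(path: str | Path):
    """Read a SAM file written by :func:`write_sam` back into records."""
    grouped: dict = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            hit = Hit(
                aln.reference_name,
                aln.reference_start,
                aln.reference_end,
                "-" if aln.is_reverse else "+",
                aln.get_tag("NM") if aln.has_tag("NM") else 0,
            )
            grouped.setdefault(aln.query_name, []).append(hit)
    records = [
        AlignmentRecord(read_id, tuple(sorted(hits, key=lambda h: (h.reference, h.start, h.strand))))
        for read_id, hits in grouped.items()
    ]
    records.sort(key=lambda r: r.read_id)
    return records
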