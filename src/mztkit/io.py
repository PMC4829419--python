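"""Plain-text I/O helpers (FASTQ via Biopython)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mztkit.readqc import Read


def write_fastq(reads, path: str | Path) -> None:
    """Write reads as 4-line FASTQ records with Phred+33 qualities."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quality)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list:
    """Read FASTQ into internal Read objects."""
    return [
        Read(rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]
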