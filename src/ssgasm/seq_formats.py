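"""Sequence and alignment I/O.

FASTA/FASTQ parsing and writing go through Biopython; SAM emission goes
through pysam. Internal coordinates are 0-based half-open everywhere in the
package — conversion to SAM's 1-based POS happens only here, at emission.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import pysam
from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "ParseError",
    "parse_sequences",
    "write_sequences",
    "write_alignments",
    "revcomp",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


class ParseError(ValueError):
    """Malformed FASTA/FASTQ input."""


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence with optional per-base qualities."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ParseError("empty sequence id")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ParseError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _detect_format(path: str) -> str:
    with open(path, "rb") as fh:
        first = fh.read(1)
    if first == b">":
        return "fasta"
    if first == b"@":
        return "fastq"
    if first == b"":
        return "empty"
    raise ParseError(f"{path}: cannot detect format from first byte {first!r}")


def parse_sequences(path: str, format: str = "auto") -> Iterator[SeqRecord]:
    """Stream :class:`SeqRecord` objects from a FASTA or FASTQ file.

    ``format='auto'`` sniffs the first byte ('>' FASTA, '@' FASTQ).
    Sequences are uppercased; multi-line FASTA is concatenated. Malformed
    records raise :class:`ParseError` naming the offending record index.
    """
    if format == "auto":
        format = _detect_format(path)
        if format == "empty":
            return
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    i = 0
    try:
        for rec in SeqIO.parse(path, format):
            i += 1
            if not rec.id:
                raise ParseError(f"{path}: record {i}: empty header")
            qual = None
            if format == "fastq":
                phred = rec.letter_annotations.get("phred_quality")
                if phred is not None:
                    qual = "".join(chr(q + 33) for q in phred)
            yield SeqRecord(rec.id, str(rec.seq).upper(), qual)
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: near record {i + 1}: {exc}") from exc


def write_sequences(records: Iterable[SeqRecord], path: str, wrap: int = 0) -> None:
    """Write records as FASTA, or FASTQ when the first record has qualities.

    One format per file (decided by the first record); in FASTQ mode a
    record without qualities gets a uniform placeholder ('I'), in FASTA
    mode qualities are dropped. ``wrap`` > 0 wraps FASTA sequence lines at
    that width. Round-trips with :func:`parse_sequences` on (id, seq).
    """
    if wrap < 0:
        raise ValueError("wrap must be >= 0")
    fastq: Optional[bool] = None
    with open(path, "w") as out:
        for rec in records:
            if fastq is None:
                fastq = rec.qual is not None
            if fastq:
                qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
                out.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")
            else:
                out.write(f">{rec.id}\n")
                if wrap:
                    for i in range(0, len(rec.seq), wrap):
                        out.write(rec.seq[i : i + wrap] + "\n")
                    if not rec.seq:
                        out.write("\n")
                else:
                    out.write(rec.seq + "\n")


def write_alignments(alns, targets, path: str) -> None:
    """Write pseudo-alignments as minimal SAM.

    ``targets`` is an iterable of (name, length) or of SeqRecord (length
    taken from the sequence). One @SQ line per target; 0-based internal
    positions become 1-based POS; FLAG carries strand (0x10) and unmapped
    (0x4) bits. Alignments referencing unknown targets raise ValueError.
    """
    tlist = []
    for t in targets:
        if isinstance(t, SeqRecord):
            tlist.append((t.id, len(t.seq)))
        else:
            tlist.append((t[0], int(t[1])))
    names = {n for n, _ in tlist}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": n, "LN": l} for n, l in tlist],
        }
    )
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for a in alns:
            seg = pysam.AlignedSegment(header)
            seg.query_name = a.query_id
            if a.target_id is None:
                seg.flag = 0x4
                seg.reference_id = -1
                seg.reference_start = -1
                seg.mapping_quality = 0
            else:
                if a.target_id not in names:
                    raise ValueError(f"alignment to unknown target {a.target_id!r}")
                seg.flag = 0x10 if a.strand == "-" else 0
                seg.reference_id = header.get_tid(a.target_id)
                seg.reference_start = a.pos
                seg.mapping_quality = a.mapq
            out.write(seg)
    # pysam leaves no trailing issues; ensure file exists even for zero alns
    if not os.path.exists(path):  # pragma: no cover - defensive
        open(path, "w").close()
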