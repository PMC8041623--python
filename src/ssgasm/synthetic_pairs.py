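"""Synthetic mate-pair libraries cut from long reads.

A spectrum of insert sizes converts each long read into many forward-
reverse 250-bp mate pairs: mate 1 is the read window [s, s+250), mate 2
the reverse complement of [s+d-250, s+d), stepped every 150 bp while the
insert d fits. Each pair remembers its read of origin, offset and library,
which is the labeling channel the scaffolding graph consumes, and a handle
on the inner read sequence used later for gap-filling consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Tuple

from .minimizer_align import Preset
from .seq_formats import SeqRecord, revcomp

__all__ = [
    "Spectrum",
    "SyntheticPair",
    "SCHEDULE_KB",
    "default_spectrum",
    "extract_synthetic_pairs",
]

# Insert-size schedule in kb: dense below 10 kb, decade steps above, 24
# entries from 0.5 kb to 200 kb for the ultralong preset; the extended tail
# (300-500 kb) is enabled for very long read length distributions.
SCHEDULE_KB: List[float] = [
    0.5, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
    15, 20, 30, 40, 50, 60, 70, 80, 90, 100,
    120, 150, 200,
]
EXTENDED_KB: List[float] = [300, 400, 500]

MATE_LEN = 250
STEP = 150


@dataclass(frozen=True)
class Spectrum:
    """Ordered synthetic libraries: (insert bp, sigma bp) with fixed mate geometry."""

    libraries: Tuple[Tuple[int, float], ...]
    mate_len: int = MATE_LEN
    step: int = STEP

    def __post_init__(self):
        inserts = [d for d, _ in self.libraries]
        if inserts != sorted(set(inserts)):
            raise ValueError("library inserts must be strictly increasing")
        for d, s in self.libraries:
            if not 500 <= d <= 500_000:
                raise ValueError(f"insert {d} outside [500, 500000]")
            if s <= 0:
                raise ValueError("sigma must be > 0")


def _sigma(insert: int) -> float:
    """Per-library sigma: 10% of the insert, floored at 50 bp."""
    return max(50.0, 0.10 * insert)


def default_spectrum(preset: Preset, read_length_n50: int) -> Spectrum:
    """The default insert-size spectrum for a technology preset.

    Ultralong nanopore (``ontlon``) uses the full 24-library 0.5-200 kb
    schedule (extended to 300/400/500 kb when the read N50 is >= 100 kb);
    every other preset truncates the schedule at the largest insert not
    exceeding twice the read-length N50.
    """
    if read_length_n50 <= 500:
        raise ValueError("read length N50 must exceed 500 bp")
    kb = list(SCHEDULE_KB)
    if preset.name == "ontlon":
        if read_length_n50 >= 100_000:
            kb += EXTENDED_KB
    else:
        kb = [x for x in kb if x * 1000 <= 2 * read_length_n50]
        if not kb:
            kb = [0.5]
    libs = tuple((int(x * 1000), _sigma(int(x * 1000))) for x in kb)
    return Spectrum(libs)


@dataclass(frozen=True)
class SyntheticPair:
    """One synthetic mate pair cut from a long read."""

    read_id: str
    offset: int  # start of mate 1 on the long read
    insert: int
    library: int  # index into the spectrum
    mate1: str
    mate2: str  # reverse-complemented
    inner: Tuple[str, int, int]  # (read id, start, end) between the mates

    @property
    def name(self) -> str:
        return f"{self.read_id}|{self.offset}|{self.insert}|{self.library}"


def extract_synthetic_pairs(
    read: SeqRecord, spectrum: Spectrum
) -> Iterator[SyntheticPair]:
    """Emit every synthetic pair of every library that fits on ``read``.

    For each library with insert d <= len(read): starts 0, 150, 300, ...
    while start + d <= len(read). Pair count per library is
    floor((L - d)/150) + 1.
    """
    L = len(read.seq)
    m = spectrum.mate_len
    for li, (d, _sig) in enumerate(spectrum.libraries):
        if d > L:
            continue
        start = 0
        while start + d <= L:
            yield SyntheticPair(
                read.id,
                start,
                d,
                li,
                read.seq[start : start + m],
                revcomp(read.seq[start + d - m : start + d]),
                (read.id, start + m, start + d - m),
            )
            start += spectrum.step


def pair_windows(read_length: int, spectrum: Spectrum) -> List[Tuple[int, int, int]]:
    """(library, mate1 start, mate2-forward start) for every pair of a read.

    The batch mapping path uses these windows to slice a read's anchor set
    instead of re-extracting minimizers per mate; mate 2's window is the
    *forward* read interval [start+d-250, start+d) whose mapping strand is
    flipped downstream.
    """
    out = []
    for li, (d, _sig) in enumerate(spectrum.libraries):
        if d > read_length:
            continue
        start = 0
        while start + d <= read_length:
            out.append((li, start, start + d - spectrum.mate_len))
            start += spectrum.step
    return out
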