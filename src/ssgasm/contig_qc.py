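"""Chimeric-contig detection and correction from short-read pair coverage.

Short pairs mapped back to the draft contigs yield the insert-size
distribution; pairs mapped within one contig at the expected orientation
and distance (within x_bar +/- 2.5 sigma) become physical fragments whose
per-base coverage exposes junctions no pair spans. Maximal runs below a
depth threshold (default 7) are low-quality intervals (LQIs), classified
by position (internal/start/end/whole), and contigs are split or trimmed
at their boundaries.

Contig termini cannot accrue full physical coverage (a fragment must start
before and end after a base to cover it), so runs that lie within one mean
insert length of a contig end are exempt from LQI calling unless coverage
is zero for more than that length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .seq_formats import SeqRecord

__all__ = [
    "InsertStats",
    "LQI",
    "estimate_insert_stats",
    "physical_coverage",
    "detect_lqi",
    "correct_contigs",
]


@dataclass(frozen=True)
class InsertStats:
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class LQI:
    contig: str
    start: int
    end: int
    kind: str  # internal | start | end | whole

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("LQI must have end > start")


def scaled_min_depth(pair_coverage: float, default: int = 7) -> int:
    """Optional low-coverage scaling of the LQI depth threshold.

    max(2, round(default * pair_coverage / 50)): at the nominal 50x pair
    coverage this is the default; toy runs at lower coverage can opt in.
    """
    return max(2, int(round(default * pair_coverage / 50.0)))


def estimate_insert_stats(distances: Iterable[int], min_pairs: int = 100) -> InsertStats:
    """Sample mean/sd of proper-pair outer distances.

    Distances larger than 10x the median are discarded as mismapped before
    computing moments. Fails when fewer than ``min_pairs`` remain.
    """
    d = np.asarray(list(distances), dtype=float)
    if d.size:
        d = d[d <= 10 * np.median(d)]
    if d.size < min_pairs:
        raise ValueError(f"too few proper pairs ({d.size} < {min_pairs})")
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return InsertStats(float(d.mean()), sd, int(d.size))


def physical_coverage(length: int, fragments: Sequence[Tuple[int, int]]) -> np.ndarray:
    """Per-base count of covering fragments via a difference array, O(n+m)."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for s, e in fragments:
        s = max(0, min(s, length))
        e = max(0, min(e, length))
        if e > s:
            diff[s] += 1
            diff[e] -= 1
    return np.cumsum(diff[:-1])


def detect_lqi(
    coverage: np.ndarray,
    contig_id: str = "",
    min_depth: int = 7,
    edge_exempt: int = 0,
) -> List[LQI]:
    """Maximal runs with coverage < min_depth, classified by location.

    ``edge_exempt``: runs lying entirely within this many bp of a contig
    terminus are tolerated unless the coverage there is zero over a span
    longer than ``edge_exempt`` (terminal edge effect of physical coverage).
    """
    n = int(coverage.size)
    if n == 0:
        return []
    low = coverage < min_depth
    out: List[LQI] = []
    i = 0
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while j < n and low[j]:
            j += 1
        keep = True
        if edge_exempt and (j <= edge_exempt or i >= n - edge_exempt):
            # run lies entirely inside a terminal zone: tolerate unless it
            # is a zero-coverage stretch longer than the zone itself
            if not int((coverage[i:j] == 0).sum()) > edge_exempt:
                keep = False
        if keep:
            touches_start = i == 0
            touches_end = j == n
            if touches_start and touches_end:
                kind = "whole"
            elif touches_start:
                kind = "start"
            elif touches_end:
                kind = "end"
            else:
                kind = "internal"
            out.append(LQI(contig_id, i, j, kind))
        i = j
    return out


def correct_contigs(
    contigs: Sequence[SeqRecord],
    lqis: Dict[str, List[LQI]],
    min_len: int = 42,
) -> Tuple[List[SeqRecord], List[Tuple[str, int, int, str, str]]]:
    """Trim/split contigs at LQI boundaries.

    Internal LQIs split the contig (LQI bases dropped); start/end LQIs trim;
    a whole-contig LQI drops it. Surviving parts shorter than ``min_len``
    (2x the alignment k by default) are dropped. Split parts are renamed
    ``<id>.1``, ``<id>.2``, ... Returns (corrected contigs, report rows
    (contig, start, end, kind, action), parts map rows
    (new id, parent id, parent start, parent end)).
    """
    out: List[SeqRecord] = []
    report: List[Tuple[str, int, int, str, str]] = []
    parts_map: List[Tuple[str, str, int, int]] = []
    for rec in contigs:
        regions = lqis.get(rec.id, [])
        if not regions:
            out.append(rec)
            parts_map.append((rec.id, rec.id, 0, len(rec.seq)))
            continue
        if any(r.kind == "whole" for r in regions):
            r = next(r for r in regions if r.kind == "whole")
            report.append((rec.id, r.start, r.end, "whole", "drop"))
            continue
        # keep the complement of the LQI intervals
        cuts = sorted((r.start, r.end) for r in regions)
        keep: List[Tuple[int, int]] = []
        pos = 0
        for s, e in cuts:
            if s > pos:
                keep.append((pos, s))
            pos = max(pos, e)
        if pos < len(rec.seq):
            keep.append((pos, len(rec.seq)))
        for r in regions:
            action = "trim" if r.kind in ("start", "end") else "split"
            report.append((rec.id, r.start, r.end, r.kind, action))
        keep = [(s, e) for s, e in keep if e - s >= min_len]
        if len(keep) == 1 and keep[0] == (0, len(rec.seq)):
            out.append(rec)
            parts_map.append((rec.id, rec.id, 0, len(rec.seq)))
        else:
            for i, (s, e) in enumerate(keep, 1):
                name = f"{rec.id}.{i}"
                out.append(SeqRecord(name, rec.seq[s:e]))
                parts_map.append((name, rec.id, s, e))
    return out, report, parts_map
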