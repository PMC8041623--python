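"""Consensus polishing with leftover contig edges, and final assembly emission.

Contig edges left out of the backbone (repeats, short sequences) carry
accurate short-read consensus and can replace noisier long-read-derived
gap sequence. The graph polisher finds long-read-coherent paths for each
filled mate edge through non-backbone contigs (bounded by an iteration
cap) and splices any path contig that aligns to the gap consensus with
identity above an expectation that grows with long-read depth (80% at
depth 1 to 99% at depth >= 20, linear in between) while covering at least
75% of the contig. The alignment polisher is the fallback: it indexes the
gap consensi with (5,17)-minimizers (frequency > 1000 excluded), chains
contig-edge hits, lays them out greedily by match count without overlap,
and splices by the same identity rule.

The final assembly is one record per line plus every unused contig edge
longer than 5 kb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

from .consensus import FillResult, edit_align, _CIG_RE
from .minimizer_align import (
    Preset,
    PseudoAlignment,
    build_index,
    map_sequence,
)
from .reduction import ReductionParams, coherent_paths
from .seq_formats import SeqRecord, revcomp
from .ssg import SSG

__all__ = [
    "PolishParams",
    "expected_identity",
    "graph_polish",
    "alignment_polish",
    "emit_assembly",
]


@dataclass(frozen=True)
class PolishParams:
    max_iterations: int = 5_000_000  # DFS edge extensions per mate edge
    identity_floor: float = 0.80  # at long-read depth 1
    identity_ceiling: float = 0.99  # at depth >= 20
    min_contig_coverage: float = 0.75
    index_w: int = 5
    index_k: int = 17
    max_minimizer_freq: int = 1000

    def __post_init__(self):
        if self.identity_floor >= self.identity_ceiling:
            raise ValueError("identity floor must be below ceiling")


def expected_identity(depth: float, params: PolishParams = PolishParams()) -> float:
    """Minimum acceptable contig identity, linear in long-read depth.

    80% at depth 1 rising to 99% at depth 20, clamped outside [1, 20].
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    d = min(max(depth, 1.0), 20.0)
    lo, hi = params.identity_floor, params.identity_ceiling
    return lo + (d - 1.0) * (hi - lo) / 19.0


@dataclass
class SpliceEvent:
    eid: int
    contig: str
    start: int  # interval replaced, in fill-region coordinates
    end: int
    identity: float
    polisher: str  # graph | alignment


def _align_contig(
    cseq: str, region: str, min_identity: float, min_cov: float
) -> Optional[Tuple[int, int, float]]:
    """Locate a contig inside a consensus region (both strands).

    Returns (region start, region end, identity) of the best placement
    passing the identity and contig-coverage cuts, else None.
    """
    best = None
    for seq in (cseq, revcomp(cseq)):
        aln = edit_align(seq, region, mode="HW")
        if aln is None:
            continue
        if best is None or aln.identity > best[0].identity:
            best = (aln, seq)
    if best is None:
        return None
    aln, seq = best
    qcols = sum(int(n) for n, op in _CIG_RE.findall(aln.cigar) if op in ("=", "X"))
    coverage = qcols / len(cseq)
    if aln.identity < min_identity or coverage < min_cov:
        return None
    return aln.target_start, aln.target_end, aln.identity


def _apply_splices(
    fill_res: FillResult,
    lines_edits: Dict[int, List[Tuple[int, int, int, str]]],
) -> None:
    """Rewrite line sequences applying (fill_start, rs, re, seq) edits.

    Edits are expressed in absolute line coordinates (fill_start + region
    offset) and applied right to left so earlier coordinates stay valid;
    fill-region coordinates of every affected line are shifted afterwards
    so later polishing passes see current offsets.
    """
    for li, edits in lines_edits.items():
        seq = fill_res.line_seqs[li]
        deltas: List[Tuple[int, int]] = []  # (absolute position, length delta)
        for start, s, e, new in sorted(edits, key=lambda x: -(x[0] + x[1])):
            a, b = start + s, start + e
            seq = seq[:a] + new + seq[b:]
            deltas.append((a, len(new) - (b - a)))
        fill_res.line_seqs[li] = seq
        for fill in fill_res.fills:
            if fill.line_idx != li:
                continue
            for p, d in deltas:
                if fill.fill_start > p:
                    fill.fill_start += d
                    fill.fill_end += d
                elif fill.fill_start <= p < fill.fill_end:
                    fill.fill_end += d


def graph_polish(
    g: SSG,
    fill_res: FillResult,
    contig_seqs: Dict[str, str],
    params: PolishParams = PolishParams(),
    red_params: ReductionParams = ReductionParams(),
) -> Tuple[List[SpliceEvent], int, Set[str]]:
    """Polish gap consensi via coherent paths through non-backbone contigs.

    Returns (splice events, number of edges skipped at the iteration cap,
    contig ids consumed). Backbone contig edges are masked during the
    search; every interior contig of a found path is aligned to the
    edge's fill region and spliced in when it meets the depth-scaled
    identity and 75% coverage rule.
    """
    events: List[SpliceEvent] = []
    capped = 0
    used: Set[str] = set()
    search_params = ReductionParams(
        tolerance_multiplier=red_params.tolerance_multiplier,
        max_path_vertices=red_params.max_path_vertices,
        max_paths_long_edge=red_params.max_paths_long_edge,
        long_edge_threshold=red_params.long_edge_threshold,
        max_iterations=params.max_iterations,
    )
    traversable = lambda cid: not g.contigs[cid].in_backbone  # noqa: E731
    edits: Dict[int, List[Tuple[int, int, int, str]]] = {}
    for fill in fill_res.fills:
        if fill.status != "filled" or fill.fill_end <= fill.fill_start:
            continue
        e = g.mate_edges[fill.eid]
        path, cap_hit = coherent_paths(
            g, e, search_params, component=None, traversable=traversable
        )
        if cap_hit:
            capped += 1
            continue
        if path is None or not path.contig_ids:
            continue
        region = fill_res.line_seqs[fill.line_idx][fill.fill_start : fill.fill_end]
        min_ident = expected_identity(fill.depth_mean, params)
        occupied: List[Tuple[int, int]] = []
        for cid in path.contig_ids:
            placed = _align_contig(
                contig_seqs[cid], region, min_ident, params.min_contig_coverage
            )
            if placed is None:
                continue
            s, t, ident = placed
            if any(s < oe and os_ < t for os_, oe in occupied):
                continue
            occupied.append((s, t))
            events.append(SpliceEvent(fill.eid, cid, s, t, ident, "graph"))
            edits.setdefault(fill.line_idx, []).append(
                (fill.fill_start, s, t, contig_seqs[cid])
            )
            used.add(cid)
    _apply_splices(fill_res, edits)
    return events, capped, used


def alignment_polish(
    g: SSG,
    fill_res: FillResult,
    contig_seqs: Dict[str, str],
    already_used: Set[str],
    params: PolishParams = PolishParams(),
) -> Tuple[List[SpliceEvent], Set[str]]:
    """Polish gap consensi by minimizer alignment of singleton contigs.

    Consensus regions are indexed with (index_w, index_k)-minimizers; each
    unplaced contig edge is chained against the index, hits are sorted by
    anchor count and laid out greedily without overlap per region, and
    each laid-out hit is spliced exactly as in the graph polisher.
    """
    regions: List[SeqRecord] = []
    region_fill: Dict[str, "object"] = {}
    for fill in fill_res.fills:
        if fill.status != "filled" or fill.fill_end <= fill.fill_start:
            continue
        seq = fill_res.line_seqs[fill.line_idx][fill.fill_start : fill.fill_end]
        if len(seq) >= params.index_k:
            name = f"edge{fill.eid}"
            regions.append(SeqRecord(name, seq))
            region_fill[name] = fill
    if not regions:
        return [], set()
    preset = Preset("polish", params.index_w, params.index_k, False, 0, 0.0)
    idx = build_index(regions, preset)

    candidates: List[Tuple[int, str, PseudoAlignment]] = []
    for cid, c in g.contigs.items():
        if c.in_backbone or cid in already_used:
            continue
        aln = map_sequence(
            SeqRecord(cid, contig_seqs[cid]), idx, preset,
            max_occ=params.max_minimizer_freq,
        )
        if aln.mapped and aln.n_anchors >= 3:
            candidates.append((aln.n_anchors, cid, aln))

    events: List[SpliceEvent] = []
    used: Set[str] = set()
    layout: Dict[str, List[Tuple[int, int]]] = {}
    edits: Dict[int, List[Tuple[int, int, int, str]]] = {}
    for n_anchors, cid, aln in sorted(candidates, key=lambda x: (-x[0], x[1])):
        fill = region_fill[aln.target_id]
        span = (aln.pos, min(aln.pos + len(contig_seqs[cid]), fill.fill_end - fill.fill_start))
        if any(span[0] < e and s < span[1] for s, e in layout.get(aln.target_id, [])):
            continue
        region = fill_res.line_seqs[fill.line_idx][fill.fill_start : fill.fill_end]
        min_ident = expected_identity(fill.depth_mean, params)
        placed = _align_contig(
            contig_seqs[cid], region, min_ident, params.min_contig_coverage
        )
        if placed is None:
            continue
        s, t, ident = placed
        if any(s < e and s2 < t for s2, e in layout.get(aln.target_id, [])):
            continue
        layout.setdefault(aln.target_id, []).append((s, t))
        events.append(SpliceEvent(fill.eid, cid, s, t, ident, "alignment"))
        edits.setdefault(fill.line_idx, []).append(
            (fill.fill_start, s, t, contig_seqs[cid])
        )
        used.add(cid)
    _apply_splices(fill_res, edits)
    return events, used


def emit_assembly(
    fill_res: FillResult,
    g: SSG,
    contig_seqs: Dict[str, str],
    used_in_polish: Set[str],
    min_extra: int = 5000,
    name_prefix: str = "ssg",
) -> List[SeqRecord]:
    """Final records: every line, plus unused contig edges > min_extra bp.

    Lines are emitted by descending length as ``<prefix>-L<n>``; leftover
    contigs keep their ids. A contig consumed by a polisher or placed in a
    line is not re-emitted.
    """
    in_lines: Set[str] = set()
    # contigs referenced by any line are flagged during backbone assembly
    for cid, c in g.contigs.items():
        if c.in_backbone:
            in_lines.add(cid)
    out: List[SeqRecord] = []
    order = sorted(
        range(len(fill_res.line_seqs)), key=lambda i: -len(fill_res.line_seqs[i])
    )
    for n, i in enumerate(order, 1):
        out.append(SeqRecord(f"{name_prefix}-L{n}", fill_res.line_seqs[i]))
    for cid in sorted(g.contigs):
        if cid in in_lines or cid in used_in_polish:
            continue
        if len(contig_seqs[cid]) > min_extra:
            out.append(SeqRecord(cid, contig_seqs[cid]))
    return out
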