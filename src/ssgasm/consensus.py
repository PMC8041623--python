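"""Mate-edge consensus and gap filling.

Every mate edge of the backbone is spanned by at least one long read (its
label set F(e)); the gap between the two contigs it joins is therefore
filled by a consensus over the best-supporting long reads. The read
contributing the most synthetic pairs is the template; the others are
aligned to it with Myers' bit-vector edit-distance algorithm (edlib),
partitioned into non-overlapping 500-bp windows on the template, filtered
at 65% chunk identity, and per window a consensus is called from a
template-anchored alignment graph (template bases as the backbone, votes
for substitutions, deletions and insertions from the aligned chunks;
the heaviest column choice wins). The window consensi are concatenated
and the flanking contig ends are aligned into the result to find the
exact sequence boundaries — producing the realized gap sequence, whose
length the fill report compares with the SSG's estimate l(e).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .backbone import Line
from .seq_formats import revcomp
from .ssg import SSG, MateEdge

__all__ = [
    "ConsensusParams",
    "EditAlignment",
    "edit_align",
    "select_spanning_reads",
    "build_read_db",
    "window_consensus",
    "fill_gaps",
    "GapFill",
    "FillResult",
]


@dataclass(frozen=True)
class ConsensusParams:
    n_reads: int = 20  # N best long reads per edge
    window: int = 500  # POA window size (bp)
    min_chunk_identity: float = 0.65
    anchor_len: int = 2000  # contig-end anchor for boundary placement
    min_anchor_identity: float = 0.80
    flank: int = 500  # read flanks added around the pair span

    def __post_init__(self):
        if self.n_reads < 1 or self.window < 100:
            raise ValueError("need n_reads >= 1 and window >= 100")


_CIG_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class EditAlignment:
    distance: int
    cigar: str
    target_start: int
    target_end: int  # exclusive
    identity: float  # matches / aligned columns


def _cigar_stats(cigar: str) -> Tuple[int, int]:
    """(matches, columns) of an extended cigar."""
    match = cols = 0
    for n, op in _CIG_RE.findall(cigar):
        n = int(n)
        cols += n
        if op == "=":
            match += n
    return match, cols


def edit_align(
    query: str,
    target: str,
    max_dist: int = -1,
    mode: str = "NW",
) -> Optional[EditAlignment]:
    """Optimal unit-cost edit alignment (Myers bit-vector via edlib).

    ``mode``: NW global, HW infix (query located within target). Returns
    None when the distance exceeds ``max_dist`` (-1 = unbounded).
    """
    if not query or not target:
        return None
    res = edlib.align(query, target, mode=mode, task="path", k=max_dist)
    if res["editDistance"] < 0:
        return None
    s, e = res["locations"][0]
    m, c = _cigar_stats(res["cigar"])
    return EditAlignment(
        res["editDistance"], res["cigar"], s, e + 1, m / c if c else 0.0
    )


def select_spanning_reads(e: MateEdge, n: int) -> List[str]:
    """Reads sorted by descending contributed-pair count, ties by id; top n.

    The first entry is the consensus template.
    """
    if not e.read_support:
        raise RuntimeError(f"mate edge {e.eid} has no labeled reads")
    order = sorted(e.read_support.items(), key=lambda kv: (-kv[1][0], kv[0]))
    return [r for r, _ in order[:n]]


def build_read_db(
    lines: Sequence[Line],
    g: SSG,
    long_reads: Dict[str, str],
    params: ConsensusParams = ConsensusParams(),
) -> "ReadDB":
    """Per-edge read substrings in global mate-edge order.

    Lines are ordered by decreasing length, which imposes a global order on
    the mate edges and hence on the read substrings; each needed read's
    relevant interval (its synthetic-pair span plus flanks) is stored once
    per (edge, read).
    """
    db = ReadDB()
    for line in sorted(lines, key=lambda l: (-l.length, l.contigs[0][0])):
        for eid in line.mate_eids:
            e = g.mate_edges[eid]
            selected = select_spanning_reads(e, params.n_reads)
            entries = []
            missing = [r for r in selected if r not in long_reads]
            if missing:
                raise KeyError(f"reads absent from source: {sorted(missing)}")
            for rid in selected:
                cnt, s1, s2 = e.read_support[rid]
                seq = long_reads[rid]
                a = max(0, s1 - params.flank)
                b = min(len(seq), s2 + params.flank)
                entries.append((rid, seq[a:b], (a, b)))
            db.edges[eid] = entries
            db.order.append(eid)
    return db


@dataclass
class ReadDB:
    order: List[int] = field(default_factory=list)  # global mate-edge order
    edges: Dict[int, List[Tuple[str, str, Tuple[int, int]]]] = field(
        default_factory=dict
    )


_B2I = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 0}
_I2B = "ACGT"


def _cigar_runs(cigar: str):
    return [(int(n), op) for n, op in _CIG_RE.findall(cigar)]


def _window_stats(runs, t0: int, window: int) -> Dict[int, List[int]]:
    """Per-window (matches, columns) of one alignment, run-level walk."""
    stats: Dict[int, List[int]] = {}
    t = t0
    for n, op in runs:
        if op == "I":
            s = stats.setdefault(t // window, [0, 0])
            s[1] += n
            continue
        while n:
            wi = t // window
            span = min(n, (wi + 1) * window - t)
            s = stats.setdefault(wi, [0, 0])
            s[1] += span
            if op == "=":
                s[0] += span
            t += span
            n -= span
    return stats


def window_consensus(
    template: str,
    others: Sequence[str],
    params: ConsensusParams = ConsensusParams(),
) -> Tuple[str, np.ndarray]:
    """Consensus of ``others`` against ``template`` in fixed windows.

    Each read is oriented to the template, globally aligned into it, cut
    at the template's window boundaries, and filtered per window at the
    chunk-identity threshold; surviving chunks vote column-wise in a
    template-anchored alignment graph (substitution/deletion votes per
    template base, insertion votes between bases) whose heaviest path is
    the consensus. Returns (consensus, per-template-base depth of
    surviving chunks including the template). Windows with no surviving
    chunk pass the template through unchanged.
    """
    if not template:
        raise ValueError("empty consensus template")
    W = params.window
    L = len(template)
    tmpl_codes = np.array([_B2I[b] for b in template], dtype=np.int64)
    votes = np.zeros((L, 5), dtype=np.int64)  # A C G T deletion
    votes[np.arange(L), tmpl_codes] += 1  # the template's own vote
    ins_votes: Dict[int, Counter] = {}

    for other in others:
        # reads come from either genome strand: orient to the template
        fwd = edlib.align(other, template, mode="HW")["editDistance"]
        rev = edlib.align(revcomp(other), template, mode="HW")["editDistance"]
        if rev < fwd:
            other = revcomp(other)
        aln = edit_align(other, template, mode="HW")
        if aln is None:
            continue
        runs = _cigar_runs(aln.cigar)
        stats = _window_stats(runs, aln.target_start, W)
        ok = {
            wi
            for wi, (m, c) in stats.items()
            if c and m / c >= params.min_chunk_identity
        }
        if not ok:
            continue
        qcodes = np.array([_B2I[b] for b in other], dtype=np.int64)
        q = 0
        t = aln.target_start
        for n, op in runs:
            if op == "I":
                if (min(t, L - 1) // W) in ok:
                    key = min(t, L)
                    ins_votes.setdefault(key, Counter())[other[q : q + n]] += 1
                q += n
                continue
            while n:
                wi = t // W
                span = min(n, (wi + 1) * W - t, L - t)
                if span <= 0:
                    break
                if wi in ok:
                    sl = slice(t, t + span)
                    if op == "=":
                        np.add.at(votes[sl], (np.arange(span), tmpl_codes[sl]), 1)
                    elif op == "X":
                        np.add.at(
                            votes[sl], (np.arange(span), qcodes[q : q + span]), 1
                        )
                    else:  # D: deletion of template bases
                        votes[sl, 4] += 1
                if op != "D":
                    q += span
                t += span
                n -= span

    depth = votes.sum(axis=1)
    best = votes.argmax(axis=1)
    # ties between a base and deletion resolve to the base (argmax order),
    # ties between bases resolve to the smaller code: deterministic
    out: List[str] = []
    for t in range(L):
        if t in ins_votes:
            ins, n_ins = min(
                ins_votes[t].items(), key=lambda kv: (-kv[1], kv[0])
            )
            if 2 * n_ins > depth[t]:
                out.append(ins)
        if best[t] != 4:
            out.append(_I2B[best[t]])
    if L in ins_votes:
        ins, n_ins = min(ins_votes[L].items(), key=lambda kv: (-kv[1], kv[0]))
        if 2 * n_ins > depth[L - 1]:
            out.append(ins)
    return "".join(out), depth


@dataclass
class GapFill:
    eid: int
    line_idx: int
    l_e: float
    sigma_e: float
    realized: Optional[float]  # None when filling failed
    n_reads: int
    status: str  # filled | merged | unanchored
    fill_start: int = 0  # interval of consensus interior in the line sequence
    fill_end: int = 0
    depth_mean: float = 0.0


@dataclass
class FillResult:
    line_seqs: List[str]
    fills: List[GapFill]
    # eid -> consensus sequence and depth (for the polishers)
    consensus: Dict[int, Tuple[str, np.ndarray]] = field(default_factory=dict)


def _oriented(seq: str, orient: str) -> str:
    return seq if orient == "+" else revcomp(seq)


def fill_gaps(
    lines: Sequence[Line],
    db: ReadDB,
    g: SSG,
    contig_seqs: Dict[str, str],
    params: ConsensusParams = ConsensusParams(),
) -> FillResult:
    """Stitch each line into a sequence, filling gaps by consensus.

    For each matched mate edge, the two flanking contig ends (up to
    ``anchor_len`` bp) are aligned into the mate-edge consensus to find
    the sequence boundaries; the spliced line keeps every contig base
    untouched. When the anchors overlap (negative gap) the contigs are
    merged at the implied overlap. A contig end that fails to align at
    ``min_anchor_identity`` leaves a gap of l(e) N's, flagged in the
    report.
    """
    res = FillResult([], [])
    for li, line in enumerate(lines):
        pieces: List[str] = []
        first_cid, first_or = line.contigs[0]
        pieces.append(_oriented(contig_seqs[first_cid], first_or))
        cur_len = len(pieces[0])
        for i, eid in enumerate(line.mate_eids):
            e = g.mate_edges[eid]
            right_cid, right_or = line.contigs[i + 1]
            right_seq = _oriented(contig_seqs[right_cid], right_or)
            entries = db.edges.get(eid, [])
            fill = GapFill(eid, li, e.l, e.sigma, None, len(entries), "unanchored")
            done = False
            if entries:
                template = entries[0][1]
                others = [s for _, s, _ in entries[1:]]
                cons, depth = window_consensus(template, others, params)
                res.consensus[eid] = (cons, depth)
                left_anchor = pieces[-1] if len(pieces[-1]) < params.anchor_len else pieces[-1][-params.anchor_len :]
                # the template strand is arbitrary relative to the line
                placed = _place_anchors(
                    left_anchor, right_seq[: params.anchor_len], cons, params
                )
                if placed is not None:
                    cons_or, le, rs = placed
                    realized = rs - le
                    fill.realized = float(realized)
                    fill.depth_mean = float(depth.mean())
                    if realized >= 0:
                        fill.status = "filled"
                        fill.fill_start = cur_len
                        fill.fill_end = cur_len + realized
                        pieces.append(cons_or[le:rs])
                        cur_len += realized
                        pieces.append(right_seq)
                        cur_len += len(right_seq)
                    else:
                        fill.status = "merged"
                        trim = min(-realized, len(right_seq) - 1)
                        pieces.append(right_seq[int(trim) :])
                        cur_len += len(right_seq) - int(trim)
                    done = True
            if not done:
                n_gap = max(int(round(e.l)), 10)
                pieces.append("N" * n_gap)
                cur_len += n_gap
                pieces.append(right_seq)
                cur_len += len(right_seq)
            res.fills.append(fill)
        res.line_seqs.append("".join(pieces))
    return res


def _place_anchors(
    left: str, right: str, cons: str, params: ConsensusParams
) -> Optional[Tuple[str, int, int]]:
    """Locate contig-end anchors in the consensus (trying both strands).

    Returns (oriented consensus, left-anchor end, right-anchor start) or
    None when either anchor fails the identity cut.
    """
    best = None
    for cseq in (cons, revcomp(cons)):
        la = edit_align(left, cseq, mode="HW")
        ra = edit_align(right, cseq, mode="HW")
        if la is None or ra is None:
            continue
        score = la.identity + ra.identity
        if best is None or score > best[0]:
            best = (score, cseq, la, ra)
    if best is None:
        return None
    _, cseq, la, ra = best
    if (
        la.identity < params.min_anchor_identity
        or ra.identity < params.min_anchor_identity
    ):
        return None
    return cseq, la.target_end, ra.target_start
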