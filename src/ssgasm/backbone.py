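"""Assembly backbone: matching cover, lines, and long-read validation.

Ordering and orienting the contigs is a maximum-weight path cover of the
reduced SSG. Restricted to mate edges (each contig-end vertex used at most
once) this is a maximum-weight matching, here computed exactly with
Edmonds' blossom algorithm; adding back the contig edges turns the
matching into vertex-disjoint paths ("lines") after destroying any simple
cycles at their lowest-weight mate edge. Mate edges touching repeat
contigs or weighing less than ``min_weight`` (default 5) are ineligible.

Backbone validation replays the long-read evidence: contig edges, mate
edges spanned by a sufficiently long read (>= O, default 20 kb), and
reduced mate edges whose line-projected path length matches their own
length within 4*max(sigma) all become physical fragments on the line; a
matched mate edge whose junction no fragment covers is suspicious and the
line is split there when fewer than ``mlr`` (default 4) long reads
support it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .ssg import SSG, MateEdge, Vertex, head, tail

__all__ = [
    "ValidationParams",
    "MatchingResult",
    "Line",
    "matching_cover",
    "break_cycles_extract_lines",
    "validate_backbone",
    "brute_force_cover_weight",
]


@dataclass(frozen=True)
class ValidationParams:
    min_overlap: int = 20_000  # O
    min_long_reads: int = 4  # mlr: split when support < mlr


@dataclass
class MatchingResult:
    matched_eids: Set[int]
    W_S: float
    W_G: float
    exact_optimum: bool  # True when W_G is a brute-force optimum

    @property
    def ratio(self) -> float:
        return self.W_S / self.W_G if self.W_G > 0 else 1.0


@dataclass
class Line:
    """An ordered, oriented path of contigs joined by matched mate edges."""

    contigs: List[Tuple[str, str]]  # (contig id, '+'|'-')
    mate_eids: List[int]  # len == len(contigs) - 1
    starts: List[float] = field(default_factory=list)  # line coordinate per contig
    last_len: float = 0.0  # length of the final contig

    def __post_init__(self):
        if len(self.mate_eids) != len(self.contigs) - 1:
            raise ValueError("a line alternates contigs and mate edges")

    @property
    def end(self) -> float:
        return self.starts[-1] + self.last_len

    @property
    def length(self) -> float:
        return self.end


def _eligible(g: SSG, min_weight: int) -> List[MateEdge]:
    out = []
    for e in g.active_mate_edges():
        if e.w < min_weight:
            continue
        if g.contigs[e.u[0]].repeat or g.contigs[e.v[0]].repeat:
            continue
        out.append(e)
    return out


def brute_force_cover_weight(edges: Sequence[Tuple[Vertex, Vertex, float]]) -> float:
    """Exhaustive maximum-weight matching over an explicit edge list."""
    best = 0.0
    n = len(edges)
    for r in range(1, n + 1):
        for combo in combinations(range(n), r):
            used: Set[Vertex] = set()
            ok = True
            w = 0.0
            for i in combo:
                u, v, wt = edges[i]
                if u in used or v in used:
                    ok = False
                    break
                used.add(u)
                used.add(v)
                w += wt
            if ok and w > best:
                best = w
    return best


def matching_cover(
    g: SSG,
    min_weight: int = 5,
    greedy: bool = False,
    brute_force_limit: int = 16,
) -> MatchingResult:
    """Maximum-weight matching over eligible (unmasked, heavy) mate edges.

    ``greedy=True`` switches to the sort-by-weight take-if-free heuristic
    for scale experiments; the default is the exact blossom matching.
    W_G is the exhaustive optimum when there are at most
    ``brute_force_limit`` eligible edges, otherwise the total eligible
    weight (an upper bound used as the observed-quality denominator).
    """
    edges = _eligible(g, min_weight)
    matched: Set[int] = set()
    if greedy:
        used: Set[Vertex] = set()
        for e in sorted(edges, key=lambda e: (-e.w, e.eid)):
            if e.u not in used and e.v not in used:
                matched.add(e.eid)
                used.add(e.u)
                used.add(e.v)
    else:
        G = nx.Graph()
        for e in edges:
            # bundling leaves one mate edge per vertex pair; tolerate
            # unbundled input by keeping the heaviest parallel edge
            old = G.get_edge_data(e.u, e.v)
            if old is None or old["weight"] < e.w:
                G.add_edge(e.u, e.v, weight=e.w, eid=e.eid)
        mate = nx.max_weight_matching(G, maxcardinality=False)
        for u, v in mate:
            matched.add(G[u][v]["eid"])
    W_S = float(sum(g.mate_edges[i].w for i in matched))
    if len(edges) <= brute_force_limit:
        W_G = brute_force_cover_weight([(e.u, e.v, float(e.w)) for e in edges])
        exact = True
    else:
        W_G = float(sum(e.w for e in edges))
        exact = False
    for e in edges:
        e.matched = e.eid in matched
    return MatchingResult(matched, W_S, W_G, exact)


def break_cycles_extract_lines(g: SSG, matching: MatchingResult) -> List[Line]:
    """Add contig edges to the matching and split the result into lines.

    Components are simple paths or cycles (every vertex touches one contig
    edge and at most one matched mate edge); each cycle is destroyed at
    its lowest-weight mate edge (ties by edge id). Singleton contigs
    become length-1 lines. Repeat-masked contigs are excluded from lines
    entirely — they are kept aside for polishing.
    """
    # contig-level view: nodes are contigs, edges are matched mate edges;
    # every vertex carries one contig edge and at most one matched mate
    # edge, so components are simple paths or simple cycles
    H = nx.MultiGraph()
    for cid, c in g.contigs.items():
        if not c.repeat:
            H.add_node(cid)
    for eid in matching.matched_eids:
        e = g.mate_edges[eid]
        H.add_edge(e.u[0], e.v[0], eid=eid)

    for comp in list(nx.connected_components(H)):
        sub = H.subgraph(comp)
        if sub.number_of_edges() == len(comp):  # cycle
            eids = [d["eid"] for _, _, d in sub.edges(data=True)]
            drop = min(eids, key=lambda i: (g.mate_edges[i].w, i))
            e = g.mate_edges[drop]
            e.matched = False
            H.remove_edge(e.u[0], e.v[0])

    mate_at: Dict[Vertex, int] = {}
    for eid in matching.matched_eids:
        e = g.mate_edges[eid]
        if not e.matched:
            continue
        mate_at[e.u] = eid
        mate_at[e.v] = eid

    lines: List[Line] = []
    seen_c: Set[str] = set()
    for cid in sorted(g.contigs):
        if cid in seen_c or g.contigs[cid].repeat:
            continue
        # walk to a free end of this (path) component
        cur: Vertex = (cid, 0)
        while (eid := mate_at.get(cur)) is not None:
            e = g.mate_edges[eid]
            other = e.v if e.u == cur else e.u
            cur = (other[0], 1 - other[1])
        # cur = (c, end) whose end-side carries no mate edge: line start;
        # entering at tail means forward orientation
        contigs: List[Tuple[str, str]] = []
        eids: List[int] = []
        starts: List[float] = []
        pos = 0.0
        c, end = cur
        while True:
            contigs.append((c, "+" if end == 0 else "-"))
            starts.append(pos)
            seen_c.add(c)
            pos += g.contigs[c].length
            far = (c, 1 - end)
            eid = mate_at.get(far)
            if eid is None:
                break
            e = g.mate_edges[eid]
            eids.append(eid)
            other = e.v if e.u == far else e.u
            pos += e.l
            c, end = other[0], other[1]
        lines.append(
            Line(contigs, eids, starts, float(g.contigs[contigs[-1][0]].length))
        )
    return lines


def validate_backbone(
    lines: List[Line],
    g: SSG,
    path_db,
    read_lengths: Dict[str, int],
    params: ValidationParams = ValidationParams(),
) -> Tuple[List[Line], List[Tuple[int, int, str]]]:
    """Split lines at unsupported joins; returns (lines, report).

    Report rows are (mate eid, supporting read count, action).
    """
    report: List[Tuple[int, int, str]] = []
    out: List[Line] = []
    # reduced-edge projections grouped per line are found via contig->line map
    for line in lines:
        if not line.mate_eids:
            out.append(line)
            continue
        coord_of: Dict[Vertex, float] = {}
        for (cid, orient), s in zip(line.contigs, line.starts):
            L = g.contigs[cid].length
            if orient == "+":
                coord_of[tail(cid)] = s
                coord_of[head(cid)] = s + L
            else:
                coord_of[head(cid)] = s
                coord_of[tail(cid)] = s + L
        total = line.end
        n = max(int(total) + 1, 1)
        frags: List[Tuple[float, float]] = []
        # (a) contig fragments
        for (cid, _), s in zip(line.contigs, line.starts):
            frags.append((s, s + g.contigs[cid].length))
        # (b) mate edges spanned by long reads >= O
        junctions: List[Tuple[float, float]] = []
        for i, eid in enumerate(line.mate_eids):
            e = g.mate_edges[eid]
            a = line.starts[i] + g.contigs[line.contigs[i][0]].length
            b = line.starts[i + 1]
            lo, hi = (a, b) if a <= b else (b, a)
            junctions.append((lo, hi))
            if any(read_lengths.get(r, 0) >= params.min_overlap for r in e.labels):
                frags.append((lo, hi + 1))
        # (c) reduced edges projected onto the line
        for rec in path_db:
            if rec.u is None or rec.u not in coord_of or rec.v not in coord_of:
                continue
            if rec.l_e <= params.min_overlap:
                continue
            a, b = coord_of[rec.u], coord_of[rec.v]
            lo, hi = (a, b) if a <= b else (b, a)
            l_pf = hi - lo
            if abs(rec.l_e - l_pf) <= 4 * max(rec.sigma_e, rec.path.sigma):
                frags.append((lo, hi))
        cov = np.zeros(n + 1)
        for s, e_ in frags:
            s_i = max(0, min(int(s), n))
            e_i = max(0, min(int(np.ceil(e_)), n))
            if e_i > s_i:
                cov[s_i] += 1
                cov[e_i] -= 1
        cov = np.cumsum(cov[:-1])
        # find suspicious joins
        cut_at: List[int] = []
        for i, eid in enumerate(line.mate_eids):
            lo, hi = junctions[i]
            s_i = max(0, min(int(lo), n - 1))
            e_i = max(s_i + 1, min(int(np.ceil(hi)), n))
            covered = cov[s_i:e_i].min() > 0
            e = g.mate_edges[eid]
            support = len(e.labels)
            if not covered:
                if support < params.min_long_reads:
                    cut_at.append(i)
                    report.append((eid, support, "split"))
                else:
                    report.append((eid, support, "kept"))
        if not cut_at:
            out.append(line)
            continue
        # split the line at the cut joins
        prev = 0
        for ci in cut_at + [len(line.mate_eids)]:
            contigs = line.contigs[prev : ci + 1]
            eids = line.mate_eids[prev:ci]
            base = line.starts[prev]
            starts = [s - base for s in line.starts[prev : ci + 1]]
            out.append(
                Line(contigs, eids, starts, float(g.contigs[contigs[-1][0]].length))
            )
            prev = ci + 1
    return out, report
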