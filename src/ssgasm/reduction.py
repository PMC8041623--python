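"""Repeat masking and transitive reduction of the SSG.

Long-range mate edges are replaced by paths of shorter mate and contig
edges that are *long-read coherent* with them: the path length matches the
edge length within 4*max(sigma(e), sigma(P)) and every edge on the path is
labeled by all of the long reads labeling e (F(e) subseteq F(e_i)). Each
successful reduction removes the edge and adds its weight to every mate
edge of the path — an implicit multiple alignment of the long reads that
span the edge, obtained without any all-versus-all overlap computation.

Repeats are masked first: the mean short-read coverage of the longest 10%
of contigs estimates single-copy coverage u_bar, and contig edges with
coverage > 1.5 * u_bar are flagged repeat and never traversed. The path
search runs inside biconnected components of the unmasked graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .ssg import SSG, MateEdge, Vertex, head, tail

__all__ = [
    "ReductionParams",
    "CoherentPath",
    "PathRecord",
    "mask_repeats",
    "biconnected_components",
    "coherent_paths",
    "transitive_reduce",
]


@dataclass(frozen=True)
class ReductionParams:
    tolerance_multiplier: float = 4.0
    max_path_vertices: int = 80
    max_paths_long_edge: int = 100
    long_edge_threshold: int = 100_000
    repeat_multiplier: float = 1.5
    unique_proxy_fraction: float = 0.10
    max_iterations: Optional[int] = None  # DFS edge extensions; None = unbounded


@dataclass
class CoherentPath:
    """Alternating mate/contig edge sequence between a reduced edge's endpoints."""

    mate_eids: List[int]
    contig_ids: List[str]  # interior contigs, in traversal order
    length: float
    sigma: float
    hits: int


@dataclass
class PathRecord:
    eid: int  # the reduced mate edge
    path: CoherentPath
    labels: FrozenSet[str]  # F(e) of the reduced edge
    l_e: float
    sigma_e: float
    w_e: int = 1
    u: Optional[Vertex] = None
    v: Optional[Vertex] = None


def mask_repeats(g: SSG, params: ReductionParams = ReductionParams()) -> int:
    """Flag contig edges with coverage > repeat_multiplier * u_bar as repeats.

    u_bar is the mean coverage of the longest ``unique_proxy_fraction`` of
    contigs (by count, at least one). Returns the number masked.
    """
    contigs = list(g.contigs.values())
    if not contigs or all(c.coverage == 0 for c in contigs):
        raise ValueError("no short-read coverage data available")
    by_len = sorted(contigs, key=lambda c: -c.length)
    n_top = max(1, int(len(by_len) * params.unique_proxy_fraction))
    u_bar = sum(c.coverage for c in by_len[:n_top]) / n_top
    n = 0
    cut = params.repeat_multiplier * u_bar
    for c in contigs:
        if c.coverage > cut:
            c.repeat = True
            n += 1
    return n


def _as_nx(g: SSG, traversable: Callable[[str], bool]) -> nx.Graph:
    G = nx.Graph()
    for c in g.contigs.values():
        if traversable(c.id):
            G.add_edge(tail(c.id), head(c.id))
    for e in g.active_mate_edges():
        if traversable(e.u[0]) and traversable(e.v[0]):
            G.add_edge(e.u, e.v)
    return G


def biconnected_components(g: SSG) -> List[Set[Vertex]]:
    """Vertex sets of the biconnected components of the unmasked SSG."""
    G = _as_nx(g, lambda cid: not g.contigs[cid].repeat)
    return [set(c) for c in nx.biconnected_components(G)]


def _edge_hits(e: MateEdge, labels: FrozenSet[str]) -> int:
    return sum(e.read_support.get(r, (0,))[0] for r in labels)


def coherent_paths(
    g: SSG,
    e: MateEdge,
    params: ReductionParams = ReductionParams(),
    component: Optional[Set[Vertex]] = None,
    traversable: Optional[Callable[[str], bool]] = None,
) -> Tuple[Optional[CoherentPath], bool]:
    """Best long-read-coherent path for mate edge ``e``, or None.

    Depth-first search from e.u to e.v over unreduced mate edges and
    traversable contig edges (default: unmasked), restricted to
    ``component`` when given. A partial path is pruned when it exceeds the
    vertex budget or is already too long
    (l(P) > l(e) and |l(e)-l(P)| > tol). Extension requires
    F(e) subseteq F(edge) for every new edge. Among complete coherent
    paths the one with the most synthetic-pair hits from e's reads wins;
    for edges >= the long-edge threshold the search stops after
    ``max_paths_long_edge`` complete paths. Returns (path, hit_cap) where
    hit_cap reports whether the iteration budget was exhausted.
    """
    if traversable is None:
        traversable = lambda cid: not g.contigs[cid].repeat  # noqa: E731
    F_e = frozenset(e.labels)
    adj = g.adjacency()
    tol_m = params.tolerance_multiplier
    long_edge = e.l >= params.long_edge_threshold
    best: Optional[CoherentPath] = None
    n_complete = 0
    iterations = 0
    cap_hit = False

    def edge_order(eid: int) -> Tuple[float, str, str]:
        m = g.mate_edges[eid]
        return (m.l, m.u[0], m.v[0])

    # stack-based DFS: frames of (vertex, mate_eids, contig_ids, l, var, visited)
    def dfs(v: Vertex, mate_eids, contig_ids, l_p, var_p, visited) -> bool:
        """Returns False to abort the whole search (budget exhausted)."""
        nonlocal best, n_complete, iterations, cap_hit
        sigma_p = var_p**0.5
        tol = tol_m * max(e.sigma, sigma_p)
        if l_p > e.l and abs(e.l - l_p) > tol:
            return True
        if len(visited) > params.max_path_vertices:
            return True
        for eid in sorted(adj.get(v, ()), key=edge_order):
            m = g.mate_edges[eid]
            if m.reduced or eid == e.eid:
                continue
            if not F_e <= m.labels:
                continue
            other = m.v if m.u == v else m.u
            if other != e.v:
                if not traversable(other[0]):
                    continue
                if component is not None and other not in component:
                    continue
            iterations += 1
            if params.max_iterations is not None and iterations > params.max_iterations:
                cap_hit = True
                return False
            l2 = l_p + m.l
            var2 = var_p + m.sigma**2
            if other == e.v:
                sigma2 = var2**0.5
                if abs(e.l - l2) <= tol_m * max(e.sigma, sigma2):
                    n_complete += 1
                    hits = sum(
                        _edge_hits(g.mate_edges[x], F_e) for x in mate_eids + [eid]
                    )
                    cand = CoherentPath(
                        mate_eids + [eid], list(contig_ids), l2, sigma2, hits
                    )
                    if best is None or cand.hits > best.hits:
                        best = cand
                    if long_edge and n_complete >= params.max_paths_long_edge:
                        return False
                continue
            # traverse the contig to its far end
            cid = other[0]
            c = g.contigs[cid]
            if F_e and not F_e <= c.labels:
                continue
            far = (cid, 1 - other[1])
            if other in visited or far in visited or far == e.u:
                continue
            ok = dfs(
                far,
                mate_eids + [eid],
                contig_ids + [cid],
                l2 + c.length,
                var2,
                visited | {other, far},
            )
            if not ok:
                return False
        return True

    dfs(e.u, [], [], 0.0, 0.0, {e.u})
    return best, cap_hit


def transitive_reduce(
    g: SSG, params: ReductionParams = ReductionParams()
) -> List[PathRecord]:
    """Reduce mate edges along coherent paths, ascending by length.

    Each reduced edge is removed (flagged) and its weight added to every
    mate edge of its path, so the active-edge weight total changes by
    exactly (k - 1) * w(e) per reduction, k being the number of mate edges
    on the path — an exact bookkeeping identity the tests verify. Returns
    the path database (one record per reduced edge, used later by backbone
    validation and gap filling).
    """
    comps = biconnected_components(g)
    # a vertex (articulation point) may sit in several components: an edge
    # is reducible only inside a component containing both its endpoints
    comp_of: Dict[Vertex, List[Set[Vertex]]] = {}
    for comp in comps:
        for v in comp:
            comp_of.setdefault(v, []).append(comp)
    db: List[PathRecord] = []
    order = sorted(
        g.active_mate_edges(), key=lambda m: (m.l, m.u[0], m.v[0], m.eid)
    )
    for e in order:
        if e.reduced:
            continue
        if g.contigs[e.u[0]].repeat or g.contigs[e.v[0]].repeat:
            continue
        comp = next(
            (c for c in comp_of.get(e.u, ()) if e.v in c), None
        )
        if comp is None:
            continue
        path, _ = coherent_paths(g, e, params, component=comp)
        if path is None:
            continue
        e.reduced = True
        for eid in path.mate_eids:
            g.mate_edges[eid].w += e.w
        db.append(
            PathRecord(e.eid, path, frozenset(e.labels), e.l, e.sigma, e.w, e.u, e.v)
        )
    return db


def dump_path_db(db: Sequence[PathRecord], path: str) -> None:
    """Append-only TSV: reduced edge, ordered edges, l(P), sigma(P), reads."""
    with open(path, "w") as out:
        for r in db:
            edges = []
            for i, meid in enumerate(r.path.mate_eids):
                edges.append(f"m{meid}")
                if i < len(r.path.contig_ids):
                    edges.append(f"c{r.path.contig_ids[i]}")
            out.write(
                f"{r.eid}\t{','.join(edges)}\t{r.path.length:.1f}"
                f"\t{r.path.sigma:.2f}\t{','.join(sorted(r.labels))}\n"
            )
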