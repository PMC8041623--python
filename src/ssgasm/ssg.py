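"""The synthetic scaffolding graph (SSG).

An undirected multigraph without self-loops: each contig C_i contributes
two vertices tail(C_i), head(C_i) joined by a contig edge of length
l(C_i); an accepted synthetic mate pair whose mates map to two different
contigs contributes a raw mate edge between the contig ends the mates
point past, with length

    l(e) = x_bar - (l(C_i) - pos_i(f)) - (l(C_j) - pos_j(r))

where x_bar is the library insert and (l(C) - pos) is each mate's overhang
(the amount of contig the fragment covers, measured from the end the
fragment exits). sigma(e) is the library sigma. Raw edges between the same
vertex pair are bundled by inverse-variance weighting:

    l(e) := p/q,  sigma(e) = sqrt(1/q),  p = sum l(e_i)/sigma(e_i)^2,
    q = sum 1/sigma(e_i)^2,  w(e) = sum w(e_i)

Every edge carries the set of long reads that generated it (the labeling
function F), plus per-read synthetic-pair counts and read-interval spans
used later for consensus-read selection and gap filling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .minimizer_align import PseudoAlignment
from .seq_formats import SeqRecord
from .synthetic_pairs import Spectrum

__all__ = [
    "Vertex",
    "ContigEdge",
    "RawMateEdge",
    "MateEdge",
    "SSG",
    "mate_edge_from_pair",
    "bundle",
    "build_ssg",
]

# a vertex is (contig id, end): end 0 = tail, 1 = head
Vertex = Tuple[str, int]


def tail(cid: str) -> Vertex:
    return (cid, 0)


def head(cid: str) -> Vertex:
    return (cid, 1)


@dataclass
class ContigEdge:
    id: str
    length: int
    coverage: float = 0.0  # mean short-read coverage c_bar_x
    repeat: bool = False
    labels: Set[str] = field(default_factory=set)  # F(c): long-read ids
    in_backbone: bool = False


@dataclass(frozen=True)
class RawMateEdge:
    u: Vertex
    v: Vertex
    l: float
    sigma: float
    read_id: str
    offset: int  # start of the pair (mate 1) on the long read
    span: Tuple[int, int]  # read interval covered by the pair

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.u[0] == self.v[0]:
            raise ValueError("mate edge endpoints must be on different contigs")


@dataclass
class MateEdge:
    eid: int
    u: Vertex
    v: Vertex
    l: float
    sigma: float
    w: int
    labels: Set[str]
    # read id -> [n pairs contributed, min span start, max span end]
    read_support: Dict[str, List[int]] = field(default_factory=dict)
    reduced: bool = False
    matched: bool = False

    @property
    def key(self) -> frozenset:
        return frozenset((self.u, self.v))


def _overhang_and_vertex(
    aln: PseudoAlignment, clen: int, mate_len: int, is_mate2: bool
) -> Tuple[float, Vertex]:
    """Fragment overhang within the contig and the contig-end vertex linked.

    The fragment travels mate1 -> mate2. Mate 1 travels in its mapped
    strand's direction; mate 2 is stored reverse-complemented so the
    fragment direction there is the opposite of its mapped strand.
    """
    direction = aln.strand if not is_mate2 else ("+" if aln.strand == "-" else "-")
    if direction == "+" and not is_mate2:
        return clen - aln.pos, head(aln.target_id)
    if direction == "-" and not is_mate2:
        return aln.pos + mate_len, tail(aln.target_id)
    if direction == "+":  # mate2, fragment entered from the tail side
        return aln.pos + mate_len, tail(aln.target_id)
    return clen - aln.pos, head(aln.target_id)


def mate_edge_from_pair(
    aln_f: PseudoAlignment,
    aln_r: PseudoAlignment,
    lib: Tuple[int, float],
    len_i: int,
    len_j: int,
    mate_len: int = 250,
    read_id: str = "",
    offset: int = 0,
) -> Optional[RawMateEdge]:
    """Raw mate edge from an accepted pair on two different contigs.

    Returns None for same-contig pairs (those feed insert re-estimation,
    not edges).
    """
    if aln_f.target_id == aln_r.target_id:
        return None
    x_bar, sigma = lib
    ov_f, vu = _overhang_and_vertex(aln_f, len_i, mate_len, is_mate2=False)
    ov_r, vv = _overhang_and_vertex(aln_r, len_j, mate_len, is_mate2=True)
    l_e = x_bar - ov_f - ov_r
    return RawMateEdge(vu, vv, l_e, sigma, read_id, offset, (offset, offset + x_bar))


def bundle(
    edges: Sequence[RawMateEdge], floor: Optional[float] = None
) -> Tuple[float, float, int]:
    """Inverse-variance bundle of raw edges sharing a vertex pair.

    Returns (l, sigma, w). ``floor`` optionally clamps a negative bundled
    length at -min(contig lengths) to keep path arithmetic finite.
    """
    if not edges:
        raise ValueError("cannot bundle zero edges")
    key = frozenset((edges[0].u, edges[0].v))
    p = q = 0.0
    for e in edges:
        if frozenset((e.u, e.v)) != key:
            raise ValueError("bundling requires identical endpoints")
        p += e.l / e.sigma**2
        q += 1.0 / e.sigma**2
    l = p / q
    if floor is not None and l < floor:
        l = floor
    return l, math.sqrt(1.0 / q), len(edges)


class SSG:
    """Contig edges + bundled, long-read-labeled mate edges."""

    def __init__(self):
        self.contigs: Dict[str, ContigEdge] = {}
        self.mate_edges: Dict[int, MateEdge] = {}
        self._next_eid = 0

    # -- construction -----------------------------------------------------
    def add_contig(self, cid: str, length: int, coverage: float = 0.0) -> None:
        if cid in self.contigs:
            raise ValueError(f"duplicate contig {cid!r}")
        self.contigs[cid] = ContigEdge(cid, length, coverage)

    def add_mate_edge(
        self,
        u: Vertex,
        v: Vertex,
        l: float,
        sigma: float,
        w: int,
        labels: Set[str],
        read_support: Optional[Dict[str, List[int]]] = None,
    ) -> MateEdge:
        if u[0] == v[0]:
            raise ValueError("self-loop / same-contig mate edge")
        for x in (u, v):
            if x[0] not in self.contigs:
                raise ValueError(f"dangling contig reference {x[0]!r}")
        e = MateEdge(self._next_eid, u, v, l, sigma, w, set(labels), read_support or {})
        self.mate_edges[e.eid] = e
        self._next_eid += 1
        return e

    # -- views ------------------------------------------------------------
    def active_mate_edges(self) -> List[MateEdge]:
        return [e for e in self.mate_edges.values() if not e.reduced]

    def adjacency(self, include_reduced: bool = False) -> Dict[Vertex, List[int]]:
        adj: Dict[Vertex, List[int]] = {}
        for cid in self.contigs:
            adj.setdefault(tail(cid), [])
            adj.setdefault(head(cid), [])
        for e in self.mate_edges.values():
            if e.reduced and not include_reduced:
                continue
            adj.setdefault(e.u, []).append(e.eid)
            adj.setdefault(e.v, []).append(e.eid)
        return adj

    def total_mate_weight(self) -> int:
        return sum(e.w for e in self.active_mate_edges())

    # -- dump/load (GFA-like TSV) ------------------------------------------
    def dump_tsv(self, path: str) -> None:
        with open(path, "w") as out:
            for c in self.contigs.values():
                out.write(
                    f"C\t{c.id}\t{c.length}\t{c.coverage:.3f}\t{int(c.repeat)}"
                    f"\t{len(c.labels)}\n"
                )
            for e in sorted(self.mate_edges.values(), key=lambda x: x.eid):
                out.write(
                    f"M\t{e.eid}\t{e.u[0]}\t{e.u[1]}\t{e.v[0]}\t{e.v[1]}"
                    f"\t{e.l:.2f}\t{e.sigma:.3f}\t{e.w}\t{len(e.labels)}"
                    f"\t{int(e.reduced)}\n"
                )

    @classmethod
    def load_tsv(cls, path: str) -> "SSG":
        g = cls()
        with open(path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                if f[0] == "C":
                    g.add_contig(f[1], int(f[2]), float(f[3]))
                    g.contigs[f[1]].repeat = bool(int(f[4]))
                elif f[0] == "M":
                    e = g.add_mate_edge(
                        (f[2], int(f[3])),
                        (f[4], int(f[5])),
                        float(f[6]),
                        float(f[7]),
                        int(f[8]),
                        set(),
                    )
                    e.reduced = bool(int(f[10]))
        return g


def build_ssg(
    contigs: Sequence[SeqRecord],
    pair_alignments: Iterable[
        Tuple[PseudoAlignment, PseudoAlignment, int, str, int]
    ],
    spectrum: Spectrum,
    short_cov: Optional[Dict[str, float]] = None,
) -> SSG:
    """Assemble the SSG from accepted synthetic-pair alignments.

    ``pair_alignments`` yields (aln_mate1, aln_mate2, library index,
    long-read id, offset on read). Same-contig pairs only label the contig;
    inter-contig pairs become raw mate edges, grouped by vertex pair and
    bundled. Contig labels F(c) take the union of reads with a mate mapped
    on the contig (within or straddling).
    """
    g = SSG()
    lengths: Dict[str, int] = {}
    for rec in contigs:
        cov = (short_cov or {}).get(rec.id, 0.0)
        g.add_contig(rec.id, len(rec.seq), cov)
        lengths[rec.id] = len(rec.seq)

    raw: Dict[frozenset, List[RawMateEdge]] = {}
    for a1, a2, lib_i, read_id, offset in pair_alignments:
        for a in (a1, a2):
            if a.target_id not in lengths:
                raise ValueError(f"alignment to unknown contig {a.target_id!r}")
            g.contigs[a.target_id].labels.add(read_id)
        lib = spectrum.libraries[lib_i]
        e = mate_edge_from_pair(
            a1,
            a2,
            lib,
            lengths[a1.target_id],
            lengths[a2.target_id],
            spectrum.mate_len,
            read_id,
            offset,
        )
        if e is None:
            continue
        raw.setdefault(frozenset((e.u, e.v)), []).append(e)

    for key, edges in raw.items():
        (ci, _), (cj, _) = tuple(key)
        floor = -float(min(lengths[ci], lengths[cj]))
        l, sigma, w = bundle(edges, floor=floor)
        labels = {e.read_id for e in edges}
        support: Dict[str, List[int]] = {}
        for e in edges:
            s = support.setdefault(e.read_id, [0, e.span[0], e.span[1]])
            s[0] += 1
            s[1] = min(s[1], e.span[0])
            s[2] = max(s[2], e.span[1])
        me = g.add_mate_edge(edges[0].u, edges[0].v, l, sigma, w, labels, support)
        del me  # bundled edge registered
    return g
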