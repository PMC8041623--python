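"""Synthetic genomes, reads and draft contigs with known ground truth.

Every generator is a pure function of its arguments and an integer seed, so
downstream stages (alignment, chimera splitting, scaffolding, gap filling)
can be tested against exact truth tables. The long-read simulator draws
lengths from a truncated log-normal (heavy-tailed, Nanopore-like) and
injects substitution/indel errors with an optional homopolymer bias; short
pairs are error-free by default because accurate short reads are assumed
upstream and it is contig structure, not short-read error, that the
pipeline exercises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Tuple

import numpy as np

from .seq_formats import SeqRecord, revcomp

__all__ = [
    "SimGenome",
    "ErrorModel",
    "simulate_genome",
    "simulate_long_reads",
    "simulate_short_pairs",
    "make_draft_contigs",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimGenome:
    """A simulated genome: chromosome strings plus repeat annotations."""

    chromosomes: List[str]
    repeat_annotations: List[Tuple[int, int, int, int]]  # (chrom, start, end, family)
    seed: int

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.chromosomes)


@dataclass(frozen=True)
class ErrorModel:
    """Per-base error probabilities for long-read simulation.

    ``homopolymer_bias`` multiplies the indel rates inside homopolymer runs
    of length >= 3, mimicking the dominant error mode of nanopore basecalls.
    """

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    homopolymer_bias: float = 1.0

    def __post_init__(self):
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r <= 0.2:
                raise ValueError("error rates must lie in [0, 0.2]")
        if self.homopolymer_bias < 1.0:
            raise ValueError("homopolymer_bias must be >= 1")


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def simulate_genome(
    length: int,
    n_repeat_families: int = 0,
    repeat_len: int = 0,
    copies_per_family: int = 0,
    divergence: float = 0.0,
    seed: int = 0,
) -> SimGenome:
    """Uniform-random genome with planted, diverged repeat copies.

    Each family is one random template; ``copies_per_family`` mutated copies
    (per-base substitutions at rate ``divergence``) are planted at disjoint
    uniformly drawn loci on a single chromosome. Every copy is annotated.
    """
    rng = np.random.default_rng(seed)
    chrom = _random_seq(rng, length)
    ann: List[Tuple[int, int, int, int]] = []
    total_rep = n_repeat_families * copies_per_family * repeat_len
    if total_rep > 0.5 * length:
        warnings.warn("repeats exceed 50% of genome length", stacklevel=2)
    occupied: List[Tuple[int, int]] = []

    def place(rlen: int) -> int:
        for _ in range(1000):
            s = int(rng.integers(0, length - rlen))
            if all(s + rlen <= a or s >= b for a, b in occupied):
                occupied.append((s, s + rlen))
                return s
        raise ValueError("cannot place repeats disjointly")

    for fam in range(n_repeat_families):
        template = _random_seq(rng, repeat_len)
        for _ in range(copies_per_family):
            copy = template.copy()
            if divergence > 0:
                mut = rng.random(repeat_len) < divergence
                idx = np.flatnonzero(mut)
                if idx.size:
                    shift = rng.integers(1, 4, size=idx.size)
                    code = np.searchsorted(_BASES, copy[idx])
                    copy[idx] = _BASES[(code + shift) % 4]
            s = place(repeat_len)
            chrom[s : s + repeat_len] = copy
            ann.append((0, s, s + repeat_len, fam))
    return SimGenome([_to_str(chrom)], sorted(ann, key=lambda a: a[1]), seed)


def _inject_errors(
    codes: np.ndarray, em: ErrorModel, rng: np.random.Generator
) -> np.ndarray:
    """Apply substitutions/insertions/deletions to a 0..3 code array."""
    n = codes.size
    if n == 0:
        return codes
    ins_rate = np.full(n, em.ins_rate)
    del_rate = np.full(n, em.del_rate)
    if em.homopolymer_bias > 1.0 and (em.ins_rate > 0 or em.del_rate > 0):
        # mark positions inside homopolymer runs >= 3
        same_prev = np.concatenate(([False], codes[1:] == codes[:-1]))
        run_id = np.cumsum(~same_prev)
        counts = np.bincount(run_id)
        in_long = counts[run_id] >= 3
        ins_rate[in_long] *= em.homopolymer_bias
        del_rate[in_long] *= em.homopolymer_bias
    u = rng.random(n)
    subs = u < em.sub_rate
    dels = (u >= em.sub_rate) & (u < em.sub_rate + del_rate)
    ins = rng.random(n) < ins_rate
    out = codes.copy()
    if subs.any():
        idx = np.flatnonzero(subs)
        out[idx] = (out[idx] + rng.integers(1, 4, size=idx.size)) % 4
    # assemble with indels
    pieces: List[np.ndarray] = []
    keep = ~dels
    if not ins.any():
        return out[keep]
    ins_idx = np.flatnonzero(ins)
    ins_bases = rng.integers(0, 4, size=ins_idx.size)
    prev = 0
    for j, pos in enumerate(ins_idx):
        seg = out[prev : pos + 1][keep[prev : pos + 1]]
        pieces.append(seg)
        pieces.append(ins_bases[j : j + 1])
        prev = pos + 1
    pieces.append(out[prev:][keep[prev:]])
    return np.concatenate(pieces)


def simulate_long_reads(
    g: SimGenome,
    coverage: float,
    length_mean: int = 15000,
    length_min: int = 1000,
    em: Optional[ErrorModel] = None,
    seed: int = 0,
) -> Tuple[List[SeqRecord], List[Tuple[str, int, int, int, str]]]:
    """Simulate long reads; returns (reads, truth table).

    Truth rows are (read_id, chrom, start, end, strand) giving the
    error-free source interval. Lengths follow a log-normal truncated below
    at ``length_min`` with the requested mean; total emitted bases track
    ``coverage`` times the genome length to within ~2%.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if length_min < 1000:
        raise ValueError("length_min must be >= 1000")
    em = em or ErrorModel()
    rng = np.random.default_rng(seed)
    chrom_arrs = [np.frombuffer(c.encode(), dtype=np.uint8) for c in g.chromosomes]
    code_maps = [np.searchsorted(_BASES, a).astype(np.int8) for a in chrom_arrs]
    lens = np.array([len(c) for c in g.chromosomes], dtype=float)
    target = coverage * lens.sum()
    # log-normal with sigma 0.5; solve mu so the truncated mean ~ length_mean
    sigma = 0.5
    mu = np.log(length_mean) - sigma**2 / 2
    reads: List[SeqRecord] = []
    truth: List[Tuple[str, int, int, int, str]] = []
    emitted = 0
    i = 0
    while emitted < target:
        L = int(rng.lognormal(mu, sigma))
        L = max(L, length_min)
        ci = int(rng.choice(len(lens), p=lens / lens.sum()))
        clen = int(lens[ci])
        L = min(L, clen)
        start = int(rng.integers(0, clen - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        codes = code_maps[ci][start : start + L]
        if strand == "-":
            codes = (3 - codes)[::-1]
        codes = _inject_errors(codes.astype(np.int64), em, rng)
        seq = _to_str(_BASES[codes])
        rid = f"lr{i:06d}"
        reads.append(SeqRecord(rid, seq))
        truth.append((rid, ci, start, start + L, strand))
        emitted += L
        i += 1
    return reads, truth


def simulate_short_pairs(
    g: SimGenome,
    coverage: float,
    read_len: int = 150,
    insert_mean: int = 350,
    insert_sd: int = 20,
    seed: int = 0,
) -> Iterator[Tuple[SeqRecord, SeqRecord]]:
    """Error-free paired-end reads, forward-reverse, Normal insert sizes.

    Inserts are drawn Normal(mean, sd) truncated below at 2*read_len; pairs
    are uniform over chromosomes; mate 2 is reverse-complemented.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if insert_mean <= 2 * read_len:
        raise ValueError("insert_mean must exceed 2*read_len")
    rng = np.random.default_rng(seed)
    lens = np.array([len(c) for c in g.chromosomes], dtype=float)
    n_pairs = int(round(coverage * lens.sum() / (2 * read_len)))
    for i in range(n_pairs):
        if insert_sd > 0:
            ins = int(round(rng.normal(insert_mean, insert_sd)))
        else:
            ins = insert_mean
        ins = max(ins, 2 * read_len)
        ci = int(rng.choice(len(lens), p=lens / lens.sum()))
        chrom = g.chromosomes[ci]
        if ins > len(chrom):
            continue
        start = int(rng.integers(0, len(chrom) - ins + 1))
        frag = chrom[start : start + ins]
        m1 = frag[:read_len]
        m2 = revcomp(frag[-read_len:])
        yield (SeqRecord(f"sp{i:07d}/1", m1), SeqRecord(f"sp{i:07d}/2", m2))


@dataclass(frozen=True)
class DraftTruth:
    """Ground truth for a simulated draft contig set."""

    # contig id -> (chrom, start, end) in truth order per chromosome
    intervals: dict = field(default_factory=dict)
    # contig id -> position of the chimeric junction within the contig (bp)
    chimera_junctions: dict = field(default_factory=dict)
    # contig ids of fragments withheld from the draft (unassembled regions)
    dropped: tuple = ()


def make_draft_contigs(
    g: SimGenome,
    n_breaks: int,
    n_chimeras: int = 0,
    seed: int = 0,
    drop_frac: float = 0.0,
    min_chimera_sep: int = 50000,
) -> Tuple[List[SeqRecord], DraftTruth]:
    """Fragment the genome into draft contigs, optionally with chimeras.

    The genome is cut at ``n_breaks`` random positions. ``n_chimeras``
    contigs are then formed by concatenating two non-adjacent fragments
    whose loci lie >= ``min_chimera_sep`` apart (junction recorded).
    ``drop_frac`` withholds that fraction of internal fragments from the
    output, emulating regions a short-read assembler fails to assemble;
    with ``drop_frac=0`` and ``n_chimeras=0`` the contigs tile the genome
    exactly.
    """
    rng = np.random.default_rng(seed)
    frags: List[Tuple[int, int, int]] = []  # (chrom, start, end)
    lens = [len(c) for c in g.chromosomes]
    total = sum(lens)
    # distribute breaks over chromosomes proportionally to length
    for ci, clen in enumerate(lens):
        nb = int(round(n_breaks * clen / total))
        cuts = np.sort(rng.choice(np.arange(1, clen), size=min(nb, clen - 1), replace=False))
        bounds = np.concatenate(([0], cuts, [clen]))
        for s, e in zip(bounds[:-1], bounds[1:]):
            frags.append((ci, int(s), int(e)))
    if n_chimeras * 2 > len(frags):
        raise ValueError("more chimeric fragments requested than available")

    truth = DraftTruth({}, {}, ())
    used = set()
    contigs: List[SeqRecord] = []
    cid = 0

    # pair up fragments for chimeras: require distant loci
    chim_pairs: List[Tuple[int, int]] = []
    order = rng.permutation(len(frags))
    for a in order:
        if len(chim_pairs) == n_chimeras:
            break
        if a in used:
            continue
        for b in order:
            if b == a or b in used:
                continue
            ca, sa, ea = frags[a]
            cb, sb, eb = frags[b]
            if ca != cb or min(abs(sa - eb), abs(sb - ea)) >= min_chimera_sep:
                chim_pairs.append((a, b))
                used.add(a)
                used.add(b)
                break
    if len(chim_pairs) < n_chimeras:
        raise ValueError("cannot form the requested number of distant chimeras")

    for a, b in chim_pairs:
        ca, sa, ea = frags[a]
        cb, sb, eb = frags[b]
        seq = g.chromosomes[ca][sa:ea] + g.chromosomes[cb][sb:eb]
        name = f"ctg{cid:05d}"
        contigs.append(SeqRecord(name, seq))
        truth.intervals[name] = (ca, sa, ea)
        truth.chimera_junctions[name] = ea - sa
        cid += 1

    # remaining fragments: optionally drop some internal ones
    remaining = [i for i in range(len(frags)) if i not in used]
    dropped: List[str] = []
    internal = [
        i for i in remaining if frags[i][1] != 0 and frags[i][2] != lens[frags[i][0]]
    ]
    n_drop = int(round(drop_frac * len(internal)))
    drop_set = set(rng.choice(internal, size=n_drop, replace=False)) if n_drop else set()
    for i in remaining:
        ci, s, e = frags[i]
        if i in drop_set:
            dropped.append(f"dropped:{ci}:{s}-{e}")
            continue
        name = f"ctg{cid:05d}"
        contigs.append(SeqRecord(name, g.chromosomes[ci][s:e]))
        truth.intervals[name] = (ci, s, e)
        cid += 1
    return contigs, DraftTruth(truth.intervals, truth.chimera_junctions, tuple(dropped))
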