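"""Minimizer-based pseudo-alignment with co-linear chaining.

The aligner sketches sequences with (w,k)-minimizers over canonical
(strand-min) k-mers hashed by an invertible 64-bit mix, chains shared
minimizers per (target, strand) by a longest-strictly-increasing-
subsequence dynamic program over target positions, and scores mapping
quality from the ratio of the best and second-best chain scores:
mapq = round(60 * (1 - s2/s1)), capped at 60 — monotone decreasing in the
strength of the best secondary chain. ``covered`` is the fraction of query
bases inside the k-mer footprint of the primary chain.

Presets bundle the sketch geometry and the pair-acceptance filters for
short reads (``shortr``: (10,21)-minimizers, reject mapq <= 30 or
coverage <= 50%) and synthetic mates cut from long reads (``ontlon``/
``ontraw``/``pacraw``/``pacccs``: (5,20)-minimizers, 250-bp mates, reject
mapq <= 40 or coverage <= 65%; ``pacraw`` additionally homopolymer-
compresses before sketching).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .seq_formats import SeqRecord

__all__ = [
    "Preset",
    "PRESETS",
    "PseudoAlignment",
    "MinimizerIndex",
    "compress_homopolymers",
    "extract_minimizers",
    "build_index",
    "map_sequence",
    "map_pair",
]

MAX_OCC = 500  # minimizers more frequent than this in the index are skipped


@dataclass(frozen=True)
class Preset:
    name: str
    w: int
    k: int
    hpc: bool
    min_mapq: int  # reject at mapq <= min_mapq (strict >)
    min_cov: float  # reject at covered <= min_cov (strict >)
    synthetic_read_len: Optional[int] = None


PRESETS: Dict[str, Preset] = {
    "shortr": Preset("shortr", 10, 21, False, 30, 0.50),
    "ontlon": Preset("ontlon", 5, 20, False, 40, 0.65, 250),
    "ontraw": Preset("ontraw", 5, 20, False, 40, 0.65, 250),
    "pacraw": Preset("pacraw", 5, 20, True, 40, 0.65, 250),
    "pacccs": Preset("pacccs", 5, 20, False, 40, 0.65, 250),
}


@dataclass(frozen=True)
class PseudoAlignment:
    query_id: str
    target_id: Optional[str]  # None = unmapped
    pos: int = 0  # 0-based leftmost position on target (full-read projection)
    strand: str = "+"
    mapq: int = 0
    covered: float = 0.0
    n_anchors: int = 0
    aln_start: int = 0  # target interval actually covered by chained anchors
    aln_end: int = 0  # (soft-clip equivalent: stops where matching stops)

    @property
    def mapped(self) -> bool:
        return self.target_id is not None


# ---------------------------------------------------------------------------
# encoding / hashing / minimizer extraction
# ---------------------------------------------------------------------------

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else -> 4."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _mix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer: an invertible 64-bit integer mix."""
    z = x.astype(np.uint64)
    z = z ^ (z >> np.uint64(30))
    z = z * np.uint64(0xBF58476D1CE4E5B9)
    z = z ^ (z >> np.uint64(27))
    z = z * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return z


def compress_homopolymers(seq: str) -> Tuple[str, List[int]]:
    """Collapse maximal homopolymer runs; return (compressed, map to run starts)."""
    if not seq:
        return "", []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    keep = np.concatenate(([True], arr[1:] != arr[:-1]))
    pos = np.flatnonzero(keep)
    return arr[keep].tobytes().decode(), pos.tolist()


def _minimizer_arrays(
    seq: str, w: int, k: int, hpc: bool = False
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (hash, position, strand) arrays of the (w,k)-minimizers.

    Positions refer to the original sequence (run starts under hpc).
    Strand is 0 when the forward k-mer is the canonical one, 1 otherwise.
    """
    if hpc:
        cseq, cmap = compress_homopolymers(seq)
        h, p, s = _minimizer_arrays(cseq, w, k, hpc=False)
        if len(p):
            p = np.asarray(cmap, dtype=np.int64)[p]
        return h, p, s
    codes = _encode(seq).astype(np.int64)
    n = codes.size - k + 1
    if n < 1:
        return (
            np.empty(0, np.uint64),
            np.empty(0, np.int64),
            np.empty(0, np.int8),
        )
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    rcodes = 3 - codes
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | codes[j : j + n].astype(np.uint64)
        rev = (rev << np.uint64(2)) | rcodes[k - 1 - j : k - 1 - j + n].astype(np.uint64)
    strand = (rev < fwd).astype(np.int8)
    canon = np.where(rev < fwd, rev, fwd)
    h = _mix64(canon)
    # invalidate k-mers containing non-ACGT
    bad = np.convolve((codes >= 4).astype(np.int64), np.ones(k, np.int64), "valid") > 0
    h[bad] = np.uint64(0xFFFFFFFFFFFFFFFF)
    if n < w:
        sel = np.array([int(np.argmin(h))])
    else:
        win = np.lib.stride_tricks.sliding_window_view(h, w)
        sel = win.argmin(axis=1) + np.arange(n - w + 1)
        sel = np.unique(sel)
    good = ~bad[sel]
    sel = sel[good]
    return h[sel], sel.astype(np.int64), strand[sel]


def extract_minimizers(seq: str, w: int, k: int) -> List[Tuple[int, int, int]]:
    """(hash, position, strand) minimizers of ``seq``; [] when len(seq) < k."""
    h, p, s = _minimizer_arrays(seq, w, k)
    return list(zip((int(x) for x in h), p.tolist(), s.tolist()))


# ---------------------------------------------------------------------------
# index
# ---------------------------------------------------------------------------


class MinimizerIndex:
    """Sorted-array minimizer index over a set of target sequences."""

    def __init__(self, preset: Preset):
        self.preset = preset
        self.target_names: List[str] = []
        self.target_lengths: List[int] = []
        self._hash = np.empty(0, np.uint64)
        self._tid = np.empty(0, np.int64)
        self._tpos = np.empty(0, np.int64)
        self._tstrand = np.empty(0, np.int8)

    @property
    def n_minimizers(self) -> int:
        return self._hash.size

    def occurrences(self, h: int) -> int:
        lo = np.searchsorted(self._hash, np.uint64(h), "left")
        hi = np.searchsorted(self._hash, np.uint64(h), "right")
        return int(hi - lo)

    def lookup(
        self, qh: np.ndarray, qp: np.ndarray, qs: np.ndarray, max_occ: int = MAX_OCC
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Anchors for query minimizers: (tid, tpos, rel_strand, qpos)."""
        lo = np.searchsorted(self._hash, qh, "left")
        hi = np.searchsorted(self._hash, qh, "right")
        cnt = hi - lo
        keep = (cnt > 0) & (cnt <= max_occ)
        lo, cnt = lo[keep], cnt[keep]
        qp_k, qs_k = qp[keep], qs[keep]
        if lo.size == 0:
            e = np.empty(0, np.int64)
            return e, e, e.astype(np.int8), e
        total = int(cnt.sum())
        offs = np.arange(total, dtype=np.int64) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        idx = np.repeat(lo, cnt) + offs  # lo..lo+cnt-1 per kept query minimizer
        qpos = np.repeat(qp_k, cnt)
        qstr = np.repeat(qs_k, cnt)
        rel = (qstr ^ self._tstrand[idx]).astype(np.int8)
        return self._tid[idx], self._tpos[idx], rel, qpos


def build_index(targets: Sequence[SeqRecord], preset: Preset) -> MinimizerIndex:
    """Index all target minimizers (homopolymer-compressed when preset.hpc)."""
    idx = MinimizerIndex(preset)
    seen = set()
    hs, tids, tps, tss = [], [], [], []
    for t, rec in enumerate(targets):
        if rec.id in seen:
            raise ValueError(f"duplicate target id {rec.id!r}")
        seen.add(rec.id)
        idx.target_names.append(rec.id)
        idx.target_lengths.append(len(rec.seq))
        h, p, s = _minimizer_arrays(rec.seq, preset.w, preset.k, preset.hpc)
        hs.append(h)
        tids.append(np.full(h.size, t, dtype=np.int64))
        tps.append(p)
        tss.append(s)
    if hs:
        h = np.concatenate(hs)
        order = np.argsort(h, kind="stable")
        idx._hash = h[order]
        idx._tid = np.concatenate(tids)[order]
        idx._tpos = np.concatenate(tps)[order]
        idx._tstrand = np.concatenate(tss)[order]
    return idx


# ---------------------------------------------------------------------------
# chaining (numba kernels)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _chain_dp(qpos, key, use):  # pragma: no cover - jitted
    """LIS DP over anchors sorted by (qpos, key); returns (score, end, parents)."""
    m = qpos.size
    dp = np.ones(m, np.int64)
    par = np.full(m, -1, np.int64)
    best = 0
    bi = -1
    for a in range(m):
        if not use[a]:
            dp[a] = 0
            continue
        for b in range(a):
            if not use[b]:
                continue
            if qpos[b] < qpos[a] and key[b] < key[a] and dp[b] + 1 > dp[a]:
                dp[a] = dp[b] + 1
                par[a] = b
        if dp[a] > best:
            best = dp[a]
            bi = a
    return best, bi, par


@njit(cache=True)
def _best_alignment(tid, rel, qpos, tpos, k, qlen):  # pragma: no cover - jitted
    """Best chained alignment over anchors sorted by (tid, rel, qpos, tpos).

    Returns (tid, pos, rel, s1, s2, covered_bases, n_anchors, aln_start,
    aln_end); tid == -1 when there are no anchors. (aln_start, aln_end) is
    the target interval spanned by the chained anchors' k-mers.
    """
    n = tid.size
    if n == 0:
        return -1, 0, 0, 0, 0, 0, 0, 0, 0
    s1 = 0
    s2 = 0
    b_tid = -1
    b_rel = 0
    b_pos = 0
    b_cov = 0
    b_n = 0
    b_tlo = 0
    b_thi = 0
    i = 0
    while i < n:
        j = i
        while j < n and tid[j] == tid[i] and rel[j] == rel[i]:
            j += 1
        m = j - i
        q = qpos[i:j]
        key = np.empty(m, np.int64)
        for a in range(m):
            key[a] = tpos[i + a] if rel[i] == 0 else -tpos[i + a]
        use = np.ones(m, np.bool_)
        score, bi, par = _chain_dp(q, key, use)
        if score > 0:
            # recover chain, compute footprint and position
            chain_idx = np.empty(score, np.int64)
            c = bi
            for t in range(score - 1, -1, -1):
                chain_idx[t] = c
                c = par[c]
            cov = 0
            for t in range(score):
                if t == 0:
                    cov += k
                else:
                    d = q[chain_idx[t]] - q[chain_idx[t - 1]]
                    cov += d if d < k else k
            first = chain_idx[0]
            last = chain_idx[score - 1]
            if rel[i] == 0:
                pos = tpos[i + first] - q[first]
            else:
                pos = tpos[i + last] - (qlen - q[last] - k)
            if pos < 0:
                pos = 0
            # within-group secondary: re-chain excluding primary target span
            lo_t = tpos[i + first]
            hi_t = tpos[i + first]
            for t in range(score):
                tp = tpos[i + chain_idx[t]]
                if tp < lo_t:
                    lo_t = tp
                if tp > hi_t:
                    hi_t = tp
            for a in range(m):
                if tpos[i + a] >= lo_t - qlen and tpos[i + a] <= hi_t + qlen:
                    use[a] = False
            score2, _, _ = _chain_dp(q, key, use)
            if score > s1:
                s2 = s1 if s1 > score2 else score2
                s1 = score
                b_tid = tid[i]
                b_rel = rel[i]
                b_pos = pos
                b_cov = cov
                b_n = score
                b_tlo = lo_t
                b_thi = hi_t + k
            else:
                if score > s2:
                    s2 = score
                if score2 > s2:
                    s2 = score2
        i = j
    return b_tid, b_pos, b_rel, s1, s2, b_cov, b_n, b_tlo, b_thi


@njit(cache=True)
def _sort_and_chain(tid, rel, qpos, tpos, k, qlen):  # pragma: no cover - jitted
    keys = (
        tid * np.int64(1) * np.int64(2**44)
        + rel.astype(np.int64) * np.int64(2**43)
        + qpos * np.int64(2**22)
        + tpos % np.int64(2**22)
    )
    order = np.argsort(keys)
    return _best_alignment(
        tid[order], rel[order].astype(np.int64), qpos[order], tpos[order], k, qlen
    )


@njit(cache=True)
def _chain_windows(tid, rel, qpos, tpos, starts, mate_len, k, out):  # pragma: no cover
    """Chain each query window [starts[i], starts[i]+mate_len) of one read.

    Anchors must be sorted by qpos. ``out`` is an (n_windows, 7) int64 array
    receiving (tid, pos, rel, s1, s2, covered_bases, n_anchors) per window.
    """
    n = tid.size
    for wi in range(starts.size):
        a = starts[wi]
        lo = np.searchsorted(qpos, a, side="left")
        hi = np.searchsorted(qpos, a + mate_len - k, side="right")
        if hi <= lo:
            out[wi, 0] = -1
            continue
        res = _sort_and_chain(
            tid[lo:hi], rel[lo:hi], qpos[lo:hi] - a, tpos[lo:hi], k, mate_len
        )
        for c in range(9):
            out[wi, c] = res[c]


def _finish_alignment(
    query_id: str, idx: MinimizerIndex, res, qlen: int, k: int
) -> PseudoAlignment:
    t, pos, rel, s1, s2, covb, n_anch, tlo, thi = (int(x) for x in res)
    if t < 0 or s1 == 0:
        return PseudoAlignment(query_id, None)
    mapq = min(60, int(round(60.0 * (1.0 - s2 / s1))))
    tlen = idx.target_lengths[t]
    pos = min(max(pos, 0), max(tlen - 1, 0))
    return PseudoAlignment(
        query_id,
        idx.target_names[t],
        pos,
        "+" if rel == 0 else "-",
        mapq,
        min(1.0, covb / qlen),
        n_anch,
        max(0, tlo),
        min(thi, tlen),
    )


def map_sequence(
    read: SeqRecord, idx: MinimizerIndex, preset: Preset, max_occ: int = MAX_OCC
) -> PseudoAlignment:
    """Map one read against the index; unmapped is a valid result."""
    if (preset.w, preset.k, preset.hpc) != (
        idx.preset.w,
        idx.preset.k,
        idx.preset.hpc,
    ):
        raise ValueError("index was built with a different (w,k,hpc) geometry")
    qh, qp, qs = _minimizer_arrays(read.seq, preset.w, preset.k, preset.hpc)
    tid, tpos, rel, qpos = idx.lookup(qh, qp, qs, max_occ=max_occ)
    if tid.size == 0:
        return PseudoAlignment(read.id, None)
    res = _sort_and_chain(tid, rel, qpos, tpos, preset.k, len(read.seq))
    return _finish_alignment(read.id, idx, res, len(read.seq), preset.k)


def pair_accepted(
    a1: PseudoAlignment, a2: PseudoAlignment, preset: Preset
) -> bool:
    """Pair-level filter: both mapped, mapq and coverage strictly above preset cuts."""
    for a in (a1, a2):
        if not a.mapped or a.mapq <= preset.min_mapq or a.covered <= preset.min_cov:
            return False
    return True


def map_pair(
    mate1: SeqRecord, mate2: SeqRecord, idx: MinimizerIndex, preset: Preset
) -> Tuple[PseudoAlignment, PseudoAlignment, bool]:
    """Map both mates independently and apply the pair acceptance filter."""
    a1 = map_sequence(mate1, idx, preset)
    a2 = map_sequence(mate2, idx, preset)
    return a1, a2, pair_accepted(a1, a2, preset)
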