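"""Minimizer extraction and chaining against brute-force oracles."""

import numpy as np
import pytest

import ssgasm as S
from ssgasm.minimizer_align import (
    PRESETS,
    PseudoAlignment,
    _minimizer_arrays,
    _mix64,
    _sort_and_chain,
    compress_homopolymers,
    pair_accepted,
)
from ssgasm.seq_formats import SeqRecord, revcomp

# ---------------------------------------------------------------------------
# homopolymer compression
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "seq,comp,cmap",
    [
        ("AAACCGT", "ACGT", [0, 3, 5, 6]),
        ("ACGT", "ACGT", [0, 1, 2, 3]),
        ("", "", []),
        ("TTTTT", "T", [0]),
    ],
)
def test_compress_homopolymers(seq, comp, cmap):
    c, m = compress_homopolymers(seq)
    assert c == comp and m == cmap


# ---------------------------------------------------------------------------
# minimizer extraction vs brute force
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _pack(kmer: str) -> int:
    v = 0
    for b in kmer:
        v = (v << 2) | "ACGT".index(b)
    return v


def _hash_kmer(kmer: str) -> int:
    rc = "".join(_COMP[b] for b in reversed(kmer))
    canon = min(_pack(kmer), _pack(rc))
    return int(_mix64(np.array([canon], dtype=np.uint64))[0])


def brute_force_minimizers(seq: str, w: int, k: int):
    """Per-window minima over canonical invertible-hash k-mers."""
    n = len(seq) - k + 1
    if n < 1:
        return []
    hashes = [_hash_kmer(seq[i : i + k]) for i in range(n)]
    sel = set()
    if n < w:
        sel.add(min(range(n), key=lambda i: hashes[i]))
    else:
        for s in range(n - w + 1):
            sel.add(min(range(s, s + w), key=lambda i: hashes[i]))
    return sorted((hashes[i], i) for i in sel)


@pytest.mark.parametrize("w,k,seed", [(1, 3, 0), (3, 3, 1), (5, 7, 2), (10, 21, 3)])
def test_minimizers_match_brute_force(w, k, seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    got = sorted((int(h), int(p)) for h, p, _ in S.extract_minimizers(seq, w, k))
    assert got == brute_force_minimizers(seq, w, k)


def test_w1_selects_every_kmer():
    seq = "ACGTACGTAC"
    assert len(S.extract_minimizers(seq, 1, 3)) == len(seq) - 2


def test_single_kmer_sequence():
    assert len(S.extract_minimizers("ACGTA", 5, 5)) == 1


def test_too_short_sequence_empty():
    assert S.extract_minimizers("ACG", 5, 5) == []


def test_n_bases_never_selected():
    ms = S.extract_minimizers("ACGTNNNNACGT", 2, 4)
    assert all("N" not in "ACGTNNNNACGT"[p : p + 4] for _, p, _ in ms)


# ---------------------------------------------------------------------------
# index
# ---------------------------------------------------------------------------


def test_duplicate_target_rejected():
    t = SeqRecord("a", "ACGTACGTACGTACGTACGTACGTA")
    with pytest.raises(ValueError, match="duplicate"):
        S.build_index([t, t], PRESETS["shortr"])


def test_identical_targets_double_occurrence():
    seq = "ACGTAGGTACCTTGACGTAAGGCCA"
    idx = S.build_index(
        [SeqRecord("a", seq), SeqRecord("b", seq)], PRESETS["ontraw"]
    )
    h, p, s = _minimizer_arrays(seq, 5, 20)
    assert all(idx.occurrences(int(x)) == 2 for x in h)


def test_geometry_mismatch_rejected(unique_genome):
    idx = S.build_index(
        [SeqRecord("g", unique_genome.chromosomes[0][:1000])], PRESETS["shortr"]
    )
    with pytest.raises(ValueError, match="geometry"):
        S.map_sequence(SeqRecord("r", "ACGT" * 20), idx, PRESETS["ontraw"])


def test_self_mapping_identity(unique_genome):
    t = SeqRecord("t", unique_genome.chromosomes[0][:2000])
    idx = S.build_index([t], PRESETS["shortr"])
    a = S.map_sequence(t, idx, PRESETS["shortr"])
    assert a.target_id == "t" and a.pos == 0 and a.strand == "+"
    assert a.covered >= 0.9 and a.mapq == 60


# ---------------------------------------------------------------------------
# mapping correctness
# ---------------------------------------------------------------------------


def test_error_free_reads_map_to_truth(unique_genome):
    chrom = unique_genome.chromosomes[0]
    contigs = [SeqRecord("g", chrom)]
    idx = S.build_index(contigs, PRESETS["shortr"])
    rng = np.random.default_rng(0)
    n_ok = 0
    n = 200
    for i in range(n):
        s = int(rng.integers(0, len(chrom) - 150))
        a = S.map_sequence(SeqRecord(f"r{i}", chrom[s : s + 150]), idx, PRESETS["shortr"])
        if a.mapped and abs(a.pos - s) <= 50 and a.strand == "+":
            n_ok += 1
    assert n_ok >= 0.99 * n


def test_mapping_invariant_under_revcomp(unique_genome):
    chrom = unique_genome.chromosomes[0]
    idx = S.build_index([SeqRecord("g", chrom)], PRESETS["shortr"])
    rng = np.random.default_rng(1)
    for i in range(20):
        s = int(rng.integers(0, len(chrom) - 200))
        read = chrom[s : s + 200]
        a = S.map_sequence(SeqRecord("f", read), idx, PRESETS["shortr"])
        b = S.map_sequence(SeqRecord("r", revcomp(read)), idx, PRESETS["shortr"])
        assert (a.pos, a.mapq) == (b.pos, b.mapq)
        assert {a.strand, b.strand} == {"+", "-"}


def test_exact_two_copy_repeat_gets_mapq_zero():
    rng = np.random.default_rng(2)
    unit = "".join(rng.choice(list("ACGT"), size=1000))
    left = "".join(rng.choice(list("ACGT"), size=3000))
    mid = "".join(rng.choice(list("ACGT"), size=3000))
    right = "".join(rng.choice(list("ACGT"), size=3000))
    genome = left + unit + mid + unit + right
    idx = S.build_index([SeqRecord("g", genome)], PRESETS["shortr"])
    read = SeqRecord("rep", unit[200:700])  # strictly interior to both copies
    a = S.map_sequence(read, idx, PRESETS["shortr"])
    assert a.mapped and a.mapq == 0  # s2 == s1 by symmetry


def test_no_shared_minimizers_unmapped(unique_genome):
    idx = S.build_index(
        [SeqRecord("g", unique_genome.chromosomes[0][:5000])], PRESETS["shortr"]
    )
    a = S.map_sequence(SeqRecord("r", "A" * 100), idx, PRESETS["shortr"])
    assert not a.mapped


# ---------------------------------------------------------------------------
# chaining kernel vs brute-force DP
# ---------------------------------------------------------------------------


def brute_force_best_chain(tid, rel, qpos, tpos):
    """Exhaustive longest chain per (target, strand) group via O(n^2) DP."""
    best = 0
    groups = {}
    for i in range(len(tid)):
        groups.setdefault((tid[i], rel[i]), []).append((qpos[i], tpos[i]))
    for (t, r), anchors in groups.items():
        anchors.sort()
        keys = [tp if r == 0 else -tp for _, tp in anchors]
        qs = [q for q, _ in anchors]
        n = len(anchors)
        dp = [1] * n
        for i in range(n):
            for j in range(i):
                if qs[j] < qs[i] and keys[j] < keys[i]:
                    dp[i] = max(dp[i], dp[j] + 1)
        best = max(best, max(dp))
    return best


@pytest.mark.parametrize("seed", range(8))
def test_chain_score_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 200))
    tid = rng.integers(0, 3, size=n).astype(np.int64)
    rel = rng.integers(0, 2, size=n).astype(np.int8)
    qpos = rng.integers(0, 500, size=n).astype(np.int64)
    tpos = rng.integers(0, 5000, size=n).astype(np.int64)
    res = _sort_and_chain(tid, rel, qpos, tpos, 21, 500)
    assert res[3] == brute_force_best_chain(tid, rel, qpos, tpos)


# ---------------------------------------------------------------------------
# pair filters
# ---------------------------------------------------------------------------


def _aln(mapq, covered):
    return PseudoAlignment("q", "t", 0, "+", mapq, covered, 5)


@pytest.mark.parametrize(
    "preset,m1,c1,m2,c2,accept",
    [
        ("shortr", 31, 0.6, 45, 0.9, True),
        ("shortr", 30, 0.9, 45, 0.9, False),  # rejection is <= 30
        ("shortr", 31, 0.50, 45, 0.9, False),  # coverage <= 50% rejected
        ("ontraw", 41, 0.66, 45, 0.9, True),
        ("ontraw", 40, 0.9, 45, 0.9, False),
        ("ontraw", 45, 0.65, 45, 0.9, False),  # exactly 65% rejected
    ],
)
def test_pair_acceptance_thresholds(preset, m1, c1, m2, c2, accept):
    assert pair_accepted(_aln(m1, c1), _aln(m2, c2), PRESETS[preset]) is accept


def test_unmapped_mate_rejects_pair():
    assert not pair_accepted(
        _aln(60, 0.9), PseudoAlignment("q", None), PRESETS["shortr"]
    )


def test_preset_table_contract():
    assert (PRESETS["shortr"].w, PRESETS["shortr"].k) == (10, 21)
    for name in ("ontlon", "ontraw", "pacraw", "pacccs"):
        p = PRESETS[name]
        assert (p.w, p.k, p.synthetic_read_len) == (5, 20, 250)
        assert (p.min_mapq, p.min_cov) == (40, 0.65)
    assert PRESETS["pacraw"].hpc and not PRESETS["pacccs"].hpc


def test_hpc_positions_refer_to_original():
    seq = "AAACGGGTTAC" * 5
    ms = _minimizer_arrays(seq, 2, 4, hpc=True)
    comp, cmap = compress_homopolymers(seq)
    assert set(ms[1].tolist()) <= set(cmap)
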