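"""Edit alignment, windowed consensus and gap filling."""

import numpy as np
import pytest

from ssgasm.backbone import Line
from ssgasm.consensus import (
    build_read_db,
    edit_align,
    fill_gaps,
    select_spanning_reads,
    window_consensus,
)
from ssgasm.seq_formats import revcomp
from ssgasm.ssg import SSG, head, tail


# ---------------------------------------------------------------------------
# edit_align vs a full dynamic-programming oracle
# ---------------------------------------------------------------------------


def dp_edit_distance(a: str, b: str) -> int:
    """Textbook O(nm) unit-cost edit distance."""
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, 1):
        cur = np.empty(len(b) + 1, dtype=np.int64)
        cur[0] = i
        sub = prev[:-1] + (np.frombuffer(b.encode(), dtype=np.uint8) != ord(ca))
        for j in range(1, len(b) + 1):
            cur[j] = min(sub[j - 1], prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return int(prev[-1])


def test_edit_align_trivial_cases():
    a = edit_align("ACGT" * 250, "ACGT" * 250)
    assert a.distance == 0 and a.identity == 1.0
    assert edit_align("ACGT", "AGT").distance == 1
    assert edit_align("", "ACGT") is None


def test_edit_align_max_dist_bound():
    assert edit_align("AAAA", "TTTT", max_dist=2) is None


def test_edit_align_matches_dp_oracle_on_random_pairs():
    rng = np.random.default_rng(17)
    for _ in range(500):
        n, m = rng.integers(1, 300, size=2)
        a = "".join(rng.choice(list("ACGT"), size=n))
        b = "".join(rng.choice(list("ACGT"), size=m))
        assert edit_align(a, b).distance == dp_edit_distance(a, b)


def test_edit_distance_equals_path_cost():
    rng = np.random.default_rng(18)
    a = "".join(rng.choice(list("ACGT"), size=120))
    b = "".join(rng.choice(list("ACGT"), size=100))
    aln = edit_align(a, b)
    from ssgasm.consensus import _CIG_RE

    cost = sum(int(n) for n, op in _CIG_RE.findall(aln.cigar) if op in "XID")
    assert cost == aln.distance


# ---------------------------------------------------------------------------
# read selection and read db
# ---------------------------------------------------------------------------


def _edge_with_reads(g, n_reads, cid_a="A", cid_b="B"):
    support = {
        f"r{i:02d}": [n_reads - i, 100 * i, 100 * i + 4000] for i in range(n_reads)
    }
    return g.add_mate_edge(
        head(cid_a), tail(cid_b), 500, 100.0, 10,
        set(support), support,
    )


def test_select_spanning_reads_top_n_and_template():
    g = SSG()
    g.add_contig("A", 1000, 30.0)
    g.add_contig("B", 1000, 30.0)
    e = _edge_with_reads(g, 30)
    sel = select_spanning_reads(e, 20)
    assert len(sel) == 20
    assert sel[0] == "r00"  # max contributor is the template


def test_select_spanning_reads_tie_by_id():
    g = SSG()
    g.add_contig("A", 1000, 30.0)
    g.add_contig("B", 1000, 30.0)
    e = g.add_mate_edge(
        head("A"), tail("B"), 500, 100.0, 4,
        {"zz", "aa"}, {"zz": [2, 0, 1000], "aa": [2, 0, 1000]},
    )
    assert select_spanning_reads(e, 2) == ["aa", "zz"]


def test_read_db_global_order_longest_line_first():
    g = SSG()
    for cid in "ABCD":
        g.add_contig(cid, 1000, 30.0)
    e1 = _edge_with_reads(g, 3, "A", "B")
    e2 = _edge_with_reads(g, 3, "C", "D")
    short = Line([("A", "+"), ("B", "+")], [e1.eid], [0.0, 1500.0], 1000.0)
    long_ = Line([("C", "+"), ("D", "+")], [e2.eid], [0.0, 49_000.0], 1000.0)
    reads = {f"r{i:02d}": "ACGT" * 2000 for i in range(3)}
    db = build_read_db([short, long_], g, reads)
    assert db.order == [e2.eid, e1.eid]  # 50-kb line first


def test_read_db_missing_read_raises():
    g = SSG()
    g.add_contig("A", 1000, 30.0)
    g.add_contig("B", 1000, 30.0)
    e = _edge_with_reads(g, 2)
    line = Line([("A", "+"), ("B", "+")], [e.eid], [0.0, 1500.0], 1000.0)
    with pytest.raises(KeyError, match="absent"):
        build_read_db([line], g, {"r00": "ACGT" * 2000})


# ---------------------------------------------------------------------------
# window consensus
# ---------------------------------------------------------------------------


def _mutate(rng, seq, rate):
    out = []
    for b in seq:
        r = rng.random()
        if r < rate * 0.5:
            out.append(rng.choice([c for c in "ACGT" if c != b]))
        elif r < rate * 0.75:
            continue  # deletion
        elif r < rate:
            out.append(b)
            out.append(rng.choice(list("ACGT")))
        else:
            out.append(b)
    return "".join(out)


def test_identical_copies_reproduce_template():
    rng = np.random.default_rng(31)
    t = "".join(rng.choice(list("ACGT"), size=1500))
    cons, depth = window_consensus(t, [t] * 19)
    assert cons == t
    assert depth.min() == 20


def test_noisy_copies_recover_truth():
    rng = np.random.default_rng(32)
    truth = "".join(rng.choice(list("ACGT"), size=2000))
    template = _mutate(rng, truth, 0.05)
    others = [_mutate(rng, truth, 0.05) for _ in range(15)]
    cons, _ = window_consensus(template, others)
    d = edit_align(cons, truth).distance
    assert d / len(truth) <= 0.005


def test_reverse_strand_reads_are_oriented():
    rng = np.random.default_rng(33)
    truth = "".join(rng.choice(list("ACGT"), size=1200))
    template = _mutate(rng, truth, 0.05)
    others = [
        revcomp(_mutate(rng, truth, 0.05)) if i % 2 else _mutate(rng, truth, 0.05)
        for i in range(14)
    ]
    cons, _ = window_consensus(template, others)
    assert edit_align(cons, truth).distance / len(truth) <= 0.005


def test_low_identity_chunk_excluded():
    rng = np.random.default_rng(34)
    truth = "".join(rng.choice(list("ACGT"), size=600))
    junk = "".join(rng.choice(list("ACGT"), size=600))  # unrelated: ~50% identity
    cons, depth = window_consensus(truth, [truth] * 5 + [junk])
    assert cons == truth
    assert depth.max() <= 6  # the junk read contributed no votes


def test_empty_template_rejected():
    with pytest.raises(ValueError):
        window_consensus("", ["ACGT"])


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------


def _gap_fixture(unique_genome, gap, a=(2000, 12_000), b_end=30_000, err=0.0, seed=41):
    """Two contigs with a known gap, spanned by reads; returns fill result."""
    rng = np.random.default_rng(seed)
    chrom = unique_genome.chromosomes[0]
    b_start = a[1] + gap
    contigs = {
        "A": chrom[a[0] : a[1]],
        "B": chrom[b_start:b_end],
    }
    g = SSG()
    g.add_contig("A", len(contigs["A"]), 30.0)
    g.add_contig("B", len(contigs["B"]), 30.0)
    # reads spanning the junction region
    reads = {}
    support = {}
    for i in range(8):
        s = a[1] - 4000 - 37 * i
        e_ = b_start + 4000 + 41 * i
        seq = chrom[max(s, 0) : e_]
        if err:
            seq = _mutate(rng, seq, err)
        if i % 2:
            seq = revcomp(seq)
        rid = f"lr{i}"
        reads[rid] = seq
        support[rid] = [8 - i, 1000, len(seq) - 1000]
    e = g.add_mate_edge(
        head("A"), tail("B"), float(gap), max(50.0, abs(gap) * 0.1), 10,
        set(support), support,
    )
    line = Line(
        [("A", "+"), ("B", "+")],
        [e.eid],
        [0.0, len(contigs["A"]) + gap],
        float(len(contigs["B"])),
    )
    db = build_read_db([line], g, reads)
    res = fill_gaps([line], db, g, contigs)
    return res, chrom, contigs, (a, b_start, b_end)


def test_fill_recovers_known_gap(unique_genome):
    res, chrom, contigs, (a, b_start, b_end) = _gap_fixture(unique_genome, 5000)
    (fill,) = res.fills
    assert fill.status == "filled"
    assert fill.realized == pytest.approx(5000, abs=4 * fill.sigma_e)
    # error-free reads: the line reconstructs the genome interval exactly
    assert res.line_seqs[0] == chrom[a[0] : b_end]


def test_fill_with_noisy_reads_close_to_truth(unique_genome):
    res, chrom, contigs, (a, b_start, b_end) = _gap_fixture(
        unique_genome, 3000, err=0.05
    )
    (fill,) = res.fills
    assert fill.status == "filled"
    d = edit_align(res.line_seqs[0], chrom[a[0] : b_end]).distance
    assert d / 3000 < 0.02  # errors only in the filled interior


def test_negative_gap_merges_contigs(unique_genome):
    res, chrom, contigs, (a, b_start, b_end) = _gap_fixture(unique_genome, -400)
    (fill,) = res.fills
    assert fill.status == "merged"
    assert fill.realized == pytest.approx(-400, abs=30)
    assert res.line_seqs[0] == chrom[a[0] : b_end]


def test_contig_bases_never_rewritten(unique_genome):
    res, chrom, contigs, _ = _gap_fixture(unique_genome, 5000, err=0.05)
    assert contigs["A"][-500:] in res.line_seqs[0]
    assert contigs["B"][:500] in res.line_seqs[0]


def test_unanchorable_gap_becomes_Ns(unique_genome):
    """Reads that do not span the gap leave an N gap flagged in the report."""
    rng = np.random.default_rng(55)
    chrom = unique_genome.chromosomes[0]
    contigs = {"A": chrom[0:10_000], "B": chrom[15_000:25_000]}
    g = SSG()
    g.add_contig("A", 10_000, 30.0)
    g.add_contig("B", 10_000, 30.0)
    junk = "".join(rng.choice(list("ACGT"), size=3000))
    support = {"bad": [5, 0, 3000]}
    e = g.add_mate_edge(
        head("A"), tail("B"), 5000.0, 400.0, 10, {"bad"}, support
    )
    line = Line([("A", "+"), ("B", "+")], [e.eid], [0.0, 15_000.0], 10_000.0)
    db = build_read_db([line], g, {"bad": junk})
    res = fill_gaps([line], db, g, contigs)
    (fill,) = res.fills
    assert fill.status == "unanchored"
    assert "N" * 100 in res.line_seqs[0]
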