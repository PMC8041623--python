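"""End-to-end hybrid assembly orchestration.

Given draft short-read contigs, short read pairs and long reads, the
pipeline (1) maps the short pairs back to the contigs to estimate insert
statistics and physical coverage, (2) splits/trims chimeric contigs at
low-quality intervals, (3) extracts a spectrum of synthetic mate pairs
from the long reads and pseudo-aligns them to the corrected contigs,
(4) builds the synthetic scaffolding graph, masks repeats and
transitively reduces it, (5) computes the matching-cover backbone,
breaks cycles and validates joins with long-read physical coverage,
(6) fills the gaps by windowed consensus, (7) polishes the gap sequence
with leftover contigs, and (8) emits the final assembly.

Synthetic mates are pseudo-aligned by slicing each long read's
precomputed minimizer anchors to the mate windows (identical chaining
and filter semantics to mapping the extracted 250-bp mates, minus
window-boundary minimizer effects) — this is what makes a 30x long-read
set tractable on one CPU.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import contig_qc
from .backbone import (
    Line,
    ValidationParams,
    break_cycles_extract_lines,
    matching_cover,
    validate_backbone,
)
from .consensus import ConsensusParams, build_read_db, fill_gaps
from .minimizer_align import (
    PRESETS,
    MinimizerIndex,
    Preset,
    PseudoAlignment,
    _chain_windows,
    _minimizer_arrays,
    build_index,
    map_sequence,
)
from .polish import PolishParams, alignment_polish, emit_assembly, graph_polish
from .reduction import ReductionParams, mask_repeats, transitive_reduce
from .seq_formats import SeqRecord
from .ssg import SSG, build_ssg
from .synthetic_pairs import Spectrum, default_spectrum, pair_windows

log = logging.getLogger("ssgasm")

__all__ = [
    "PipelineConfig",
    "AssemblyResult",
    "run_pipeline",
    "n50",
    "demo_simulation",
]


def demo_simulation(seed: int):
    """The standard 1-Mb demonstration dataset.

    One chromosome with two diverged (2%) 2-kb repeat families (three
    copies each); 30x long reads (mean 15 kb, ~5% error split between
    substitutions and indels); 50x error-free 2x150-bp pairs at 350 bp
    inserts; draft contigs from 250 random breaks with a quarter of the
    internal fragments withheld (regions a short-read assembler fails to
    assemble), giving true gap sizes from tens of bp to ~10 kb. Returns
    (genome, long reads, read truth, short pairs, contigs, draft truth).
    """
    from . import simdata

    genome = simdata.simulate_genome(
        1_000_000,
        n_repeat_families=2,
        repeat_len=2000,
        copies_per_family=3,
        divergence=0.02,
        seed=seed,
    )
    em = simdata.ErrorModel(sub_rate=0.02, ins_rate=0.015, del_rate=0.015)
    reads, read_truth = simdata.simulate_long_reads(
        genome, coverage=30, length_mean=15_000, em=em, seed=seed + 1
    )
    pairs = list(simdata.simulate_short_pairs(genome, coverage=50, seed=seed + 2))
    contigs, draft_truth = simdata.make_draft_contigs(
        genome, n_breaks=250, seed=seed + 3, drop_frac=0.25
    )
    return genome, reads, read_truth, pairs, contigs, draft_truth


@dataclass
class PipelineConfig:
    preset: str = "ontraw"
    min_depth: int = 7
    min_weight: int = 5
    validation: ValidationParams = field(default_factory=ValidationParams)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    polish: PolishParams = field(default_factory=PolishParams)
    reduction: ReductionParams = field(default_factory=ReductionParams)
    spectrum: Optional[Spectrum] = None  # None = default for preset and N50
    insert_mean_hint: float = 350.0  # used only if too few pairs to estimate
    seed: int = 0


@dataclass
class AssemblyResult:
    assembly: List[SeqRecord]
    lines: List[Line]
    graph: SSG
    fills: list
    metrics: Dict[str, float]
    corrected_contigs: List[SeqRecord]
    path_db: list
    qc_report: list = field(default_factory=list)
    polish_events: list = field(default_factory=list)


def n50(lengths: Sequence[int], genome_size: Optional[int] = None) -> int:
    """N50 (or NG50 when ``genome_size`` given) of a length set."""
    ls = sorted(lengths, reverse=True)
    half = (genome_size if genome_size else sum(ls)) / 2
    acc = 0
    for l in ls:
        acc += l
        if acc >= half:
            return l
    return ls[-1] if ls else 0


def _map_short_pairs(
    pairs: Iterable[Tuple[SeqRecord, SeqRecord]],
    contigs: Sequence[SeqRecord],
    preset: Preset,
) -> Tuple[List[int], Dict[str, List[Tuple[int, int]]], Dict[str, np.ndarray]]:
    """Map pairs with the shortr preset.

    Returns (strictly filtered proper within-contig outer distances for
    insert estimation, per-contig physical fragments, per-contig
    base-coverage difference arrays). Fragments and base coverage use the
    best placement regardless of mapping quality: a pair ambiguous between
    repeat copies on *other* contigs is still evidence that *this* contig
    is contiguous, and a true chimera junction has no proper-distance
    spanning pairs under any placement; the strict mapq/coverage filter is
    kept for the insert-size estimate, which wants unambiguous pairs only.
    """
    idx = build_index(contigs, preset)
    clen = {r.id: len(r.seq) for r in contigs}
    distances: List[int] = []
    frags: Dict[str, List[Tuple[int, int]]] = {r.id: [] for r in contigs}
    basecov: Dict[str, np.ndarray] = {
        r.id: np.zeros(len(r.seq) + 1, dtype=np.int64) for r in contigs
    }
    for m1, m2 in pairs:
        a1 = map_sequence(m1, idx, preset)
        a2 = map_sequence(m2, idx, preset)
        for a, m in ((a1, m1), (a2, m2)):
            if a.mapped and a.covered > preset.min_cov:
                cov = basecov[a.target_id]
                e = min(a.pos + len(m.seq), clen[a.target_id])
                cov[a.pos] += 1
                cov[e] -= 1
        if not (a1.mapped and a2.mapped) or a1.target_id != a2.target_id:
            continue
        if a1.covered <= preset.min_cov or a2.covered <= preset.min_cov:
            continue
        rl1, rl2 = len(m1.seq), len(m2.seq)
        # proper orientation: forward mate before reverse mate
        if a1.strand == "+" and a2.strand == "-" and a2.pos + rl2 >= a1.pos:
            left, right = a1.pos, a2.pos + rl2
            cleft, cright = a1.aln_start, a2.aln_end
        elif a1.strand == "-" and a2.strand == "+" and a1.pos + rl1 >= a2.pos:
            left, right = a2.pos, a1.pos + rl1
            cleft, cright = a2.aln_start, a1.aln_end
        else:
            continue
        # fragment endpoints use the chained (soft-clip equivalent)
        # footprint so a mate straddling a chimeric junction does not
        # bridge the coverage dip with its unaligned tail
        frags[a1.target_id].append((cleft, cright))
        if a1.mapq > preset.min_mapq and a2.mapq > preset.min_mapq:
            distances.append(right - left)
    return distances, frags, basecov


def _correct_contigs_stage(
    contigs: Sequence[SeqRecord],
    distances: List[int],
    frags: Dict[str, List[Tuple[int, int]]],
    basecov: Dict[str, np.ndarray],
    cfg: PipelineConfig,
) -> Tuple[List[SeqRecord], Dict[str, float], list]:
    """LQI detection and chimera splitting; returns corrected contigs,
    per-corrected-contig mean short-read coverage, and the QC report."""
    try:
        stats = contig_qc.estimate_insert_stats(distances)
        mean, sd = stats.mean, stats.sd
    except ValueError:
        mean, sd = cfg.insert_mean_hint, cfg.insert_mean_hint * 0.1
    lo, hi = mean - 2.5 * sd, mean + 2.5 * sd
    lqis = {}
    for rec in contigs:
        good = [
            (s, e) for s, e in frags[rec.id] if lo <= e - s <= hi
        ]
        cov = contig_qc.physical_coverage(len(rec.seq), good)
        found = contig_qc.detect_lqi(
            cov, rec.id, cfg.min_depth, edge_exempt=int(mean)
        )
        if found:
            lqis[rec.id] = found
    corrected, report, parts_map = contig_qc.correct_contigs(contigs, lqis)
    # mean short-read coverage per corrected part, from parent base coverage
    short_cov: Dict[str, float] = {}
    parent_cov = {cid: np.cumsum(d[:-1]) for cid, d in basecov.items()}
    for new_id, parent, s, e in parts_map:
        arr = parent_cov[parent][s:e]
        short_cov[new_id] = float(arr.mean()) if arr.size else 0.0
    return corrected, short_cov, report


def _map_synthetic_pairs(
    long_reads: Sequence[SeqRecord],
    idx: MinimizerIndex,
    preset: Preset,
    spectrum: Spectrum,
) -> Iterable[Tuple[PseudoAlignment, PseudoAlignment, int, str, int]]:
    """Accepted synthetic-pair pseudo-alignments, batch path.

    Anchors are computed once per long read and sliced per mate window;
    mate 2 windows are the forward read interval with the mapping strand
    flipped afterwards (a canonical sketch is strand-symmetric).
    """
    m = spectrum.mate_len
    k = preset.k
    names = idx.target_names
    tlens = idx.target_lengths
    out = []
    for read in long_reads:
        wins = pair_windows(len(read.seq), spectrum)
        if not wins:
            continue
        qh, qp, qs = _minimizer_arrays(read.seq, preset.w, preset.k, preset.hpc)
        tid, tpos, rel, qpos = idx.lookup(qh, qp, qs)
        if tid.size == 0:
            continue
        libs = np.array([w[0] for w in wins], dtype=np.int64)
        s1 = np.array([w[1] for w in wins], dtype=np.int64)
        s2 = np.array([w[2] for w in wins], dtype=np.int64)
        res1 = np.empty((len(wins), 9), dtype=np.int64)
        res2 = np.empty((len(wins), 9), dtype=np.int64)
        _chain_windows(tid, rel, qpos, tpos, s1, m, k, res1)
        _chain_windows(tid, rel, qpos, tpos, s2, m, k, res2)
        for i in range(len(wins)):
            t1, p1, r1, s1a, s2a, cb1, na1 = res1[i][:7]
            t2, p2, r2, s1b, s2b, cb2, na2 = res2[i][:7]
            if t1 < 0 or t2 < 0 or s1a == 0 or s1b == 0:
                continue
            mapq1 = min(60, int(round(60.0 * (1.0 - s2a / s1a))))
            mapq2 = min(60, int(round(60.0 * (1.0 - s2b / s1b))))
            cov1 = min(1.0, cb1 / m)
            cov2 = min(1.0, cb2 / m)
            if (
                mapq1 <= preset.min_mapq
                or mapq2 <= preset.min_mapq
                or cov1 <= preset.min_cov
                or cov2 <= preset.min_cov
            ):
                continue
            li = int(libs[i])
            d = spectrum.libraries[li][0]
            a1 = PseudoAlignment(
                f"{read.id}|{s1[i]}|{d}|{li}/1",
                names[t1],
                int(min(max(p1, 0), tlens[t1] - 1)),
                "+" if r1 == 0 else "-",
                mapq1,
                cov1,
                int(na1),
            )
            # mate 2 is the reverse complement of its forward window
            a2 = PseudoAlignment(
                f"{read.id}|{s1[i]}|{d}|{li}/2",
                names[t2],
                int(min(max(p2, 0), tlens[t2] - 1)),
                "-" if r2 == 0 else "+",
                mapq2,
                cov2,
                int(na2),
            )
            out.append((a1, a2, li, read.id, int(s1[i])))
    return out


def run_pipeline(
    contigs: Sequence[SeqRecord],
    short_pairs: Iterable[Tuple[SeqRecord, SeqRecord]],
    long_reads: Sequence[SeqRecord],
    cfg: PipelineConfig = PipelineConfig(),
    genome_size: Optional[int] = None,
) -> AssemblyResult:
    """Run the full assembly pipeline in memory; returns all artifacts."""
    t0 = time.time()
    preset_short = PRESETS["shortr"]
    preset_syn = PRESETS[cfg.preset]
    metrics: Dict[str, float] = {}

    distances, frags, basecov = _map_short_pairs(short_pairs, contigs, preset_short)
    log.info("short pairs mapped: %d proper distances", len(distances))
    corrected, short_cov, qc_report = _correct_contigs_stage(
        contigs, distances, frags, basecov, cfg
    )
    metrics["n_input_contigs"] = len(contigs)
    metrics["n_corrected_contigs"] = len(corrected)
    metrics["n_qc_actions"] = len(qc_report)
    log.info("contig QC: %d -> %d contigs (%.1fs)", len(contigs), len(corrected),
             time.time() - t0)

    read_n50 = n50([len(r.seq) for r in long_reads])
    spectrum = cfg.spectrum or default_spectrum(preset_syn, read_n50)
    metrics["n_libraries"] = len(spectrum.libraries)

    idx = build_index(corrected, preset_syn)
    pair_alns = list(
        _map_synthetic_pairs(long_reads, idx, preset_syn, spectrum)
    )
    metrics["n_accepted_pairs"] = len(pair_alns)
    log.info("synthetic pairs accepted: %d (%.1fs)", len(pair_alns), time.time() - t0)

    g = build_ssg(corrected, pair_alns, spectrum, short_cov)
    metrics["n_mate_edges"] = len(g.mate_edges)
    metrics["initial_mate_weight"] = float(g.total_mate_weight())
    n_masked = mask_repeats(g, cfg.reduction)
    metrics["n_repeat_contigs"] = n_masked
    path_db = transitive_reduce(g, cfg.reduction)
    metrics["n_reduced_edges"] = len(path_db)
    log.info("SSG: %d mate edges, %d masked contigs, %d reduced (%.1fs)",
             len(g.mate_edges), n_masked, len(path_db), time.time() - t0)

    matching = matching_cover(g, cfg.min_weight)
    metrics["matching_ratio"] = matching.ratio
    metrics["W_S"] = matching.W_S
    metrics["W_G"] = matching.W_G
    lines = break_cycles_extract_lines(g, matching)
    read_lengths = {r.id: len(r.seq) for r in long_reads}
    lines, val_report = validate_backbone(
        lines, g, path_db, read_lengths, cfg.validation
    )
    metrics["n_lines"] = len(lines)
    metrics["n_validation_splits"] = sum(1 for r in val_report if r[2] == "split")
    for line in lines:
        for cid, _ in line.contigs:
            g.contigs[cid].in_backbone = True
    log.info("backbone: %d lines, ratio %.3f (%.1fs)", len(lines), matching.ratio,
             time.time() - t0)

    contig_seqs = {r.id: r.seq for r in corrected}
    reads_by_id = {r.id: r.seq for r in long_reads}
    db = build_read_db(lines, g, reads_by_id, cfg.consensus)
    fill_res = fill_gaps(lines, db, g, contig_seqs, cfg.consensus)
    n_filled = sum(1 for f in fill_res.fills if f.status in ("filled", "merged"))
    metrics["n_gaps"] = len(fill_res.fills)
    metrics["n_filled"] = n_filled
    log.info("gap filling: %d/%d (%.1fs)", n_filled, len(fill_res.fills),
             time.time() - t0)

    gp_events, gp_capped, used = graph_polish(
        g, fill_res, contig_seqs, cfg.polish, cfg.reduction
    )
    ap_events, used2 = alignment_polish(
        g, fill_res, contig_seqs, used, cfg.polish
    )
    metrics["n_graph_polish"] = len(gp_events)
    metrics["n_alignment_polish"] = len(ap_events)
    metrics["n_polish_capped"] = gp_capped

    assembly = emit_assembly(fill_res, g, contig_seqs, used | used2)
    lens = [len(r.seq) for r in assembly]
    metrics["n_records"] = len(assembly)
    metrics["total_length"] = float(sum(lens))
    metrics["n50"] = float(n50(lens))
    if genome_size:
        metrics["ng50"] = float(n50(lens, genome_size))
    metrics["elapsed_s"] = time.time() - t0
    log.info("assembly: %d records, N50 %d (%.1fs)", len(assembly),
             int(metrics["n50"]), metrics["elapsed_s"])
    return AssemblyResult(
        assembly, lines, g, fill_res, metrics, list(corrected), path_db,
        qc_report, list(gp_events) + list(ap_events),
    )
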