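# ssgasm — hybrid assembly via a synthetic scaffolding graph

`ssgasm` assembles genomes from the combination of **accurate short-read
contigs** and **long, error-prone reads** (Nanopore- or PacBio-style)
without ever computing all-versus-all long-read overlaps. It is aimed at
people building or studying hybrid assemblers: every stage is an importable,
separately testable Python module, and a bundled simulator provides genomes,
reads and draft contigs with exact ground truth so the whole pipeline runs
offline.

## The method

Long-range information is extracted from each long read as **synthetic mate
pairs**: 250-bp mates cut in forward–reverse orientation at a spectrum of
insert sizes *d* (0.5 kb up to 200 kb for ultralong reads), stepped every
150 bp. Mates are pseudo-aligned to the contigs with (w,k)-minimizers and
co-linear chaining. An accepted pair whose mates hit two contigs
C<sub>i</sub>, C<sub>j</sub> becomes a **mate edge** between contig-end
vertices with length

```
l(e) = x̄ − (l(Cᵢ) − pos_Cᵢ(f)) − (l(Cⱼ) − pos_Cⱼ(r)),     σ(e) = σ_library
```

Parallel mate edges are bundled by inverse-variance weighting
(`l = p/q`, `σ = √(1/q)` with `p = Σ l(eᵢ)/σᵢ²`, `q = Σ 1/σᵢ²`) and each
edge is labeled with the long reads that generated it (the function *F*).
This graph — the **synthetic scaffolding graph (SSG)** — is then:

1. **repeat-masked**: contig coverage above 1.5× the mean of the longest
   10% of contigs flags a repeat;
2. **transitively reduced**: a mate edge *e* is replaced by a path *P* of
   shorter edges when `|l(e) − l(P)| ≤ 4·max(σ(e), σ(P))` and
   `F(e) ⊆ F(eᵢ)` for every path edge — an implicit long-read overlap,
   with `w(e)` added to every path edge;
3. **covered by an exact maximum-weight matching** over mate edges
   (weight ≥ 5, no repeat contacts), which together with the contig edges
   yields vertex-disjoint paths — the assembly backbone **lines**;
4. **validated** against long-read physical coverage (joins not covered by
   a ≥ 20 kb overlap and supported by < 4 reads are split);
5. **gap-filled**: per mate edge, the best-supporting long reads are
   aligned to a template (Myers bit-vector via edlib), cut into 500-bp
   windows, filtered at 65% chunk identity, and a template-anchored
   alignment-graph consensus fills the gap, anchored by the flanking
   contig ends;
6. **polished**: leftover (repeat/short) contigs replace consensus
   intervals they match above a depth-scaled identity threshold (80% at
   depth 1 → 99% at depth ≥ 20, covering ≥ 75% of the contig).

## Worked example

```bash
ssgasm assemble --demo --seed 1 --out demo_out -v
```

simulates a 1-Mb genome (two diverged 2-kb repeat families), 30× long reads
(~5% error, mean 15 kb), 50× short pairs, and a fragmented draft (250
breaks, 25% of internal fragments withheld), then assembles it. It prints:

```
assembly: 42 records, total 1022492 bp, N50 695455 bp -> demo_out/assembly.fasta
```

meaning the ~190 draft contigs (NG50 ≈ 5 kb) were joined into lines with an
N50 of ~0.7 Mb — a >100-fold contiguity gain — plus unplaced contigs > 5 kb.
`demo_out/metrics.json` records per-stage counts (accepted pairs, mate
edges, reductions, matching ratio W(S)/W(G) ≈ 0.83, gaps filled);
`backbone.tsv` lists contig order/orientation/gap per line, and `ssg.tsv`
dumps the graph. The same run from Python:

```python
from ssgasm.pipeline import PipelineConfig, demo_simulation, run_pipeline
genome, reads, _, pairs, contigs, _ = demo_simulation(seed=1)
res = run_pipeline(contigs, pairs, reads, PipelineConfig(preset="ontraw"),
                   genome_size=genome.length)
print(res.metrics["ng50"], res.metrics["matching_ratio"])
```

Shorter, single-capability scripts live in `examples/`.

## Layout

```
src/ssgasm/
  seq_formats.py     FASTA/FASTQ/SAM I/O (0-based internally)
  simdata.py         genome/read/contig simulator with truth tables
  minimizer_align.py (w,k)-minimizer pseudo-aligner with presets
  synthetic_pairs.py insert-size spectrum and mate extraction
  contig_qc.py       insert stats, physical coverage, chimera splitting
  ssg.py             the scaffolding graph: mate edges, bundling, labels
  reduction.py       repeat masking, biconnectivity, transitive reduction
  backbone.py        matching cover, lines, long-read validation
  consensus.py       edit alignment, windowed consensus, gap filling
  polish.py          graph/alignment polishers, final emission
  pipeline.py        orchestration; cli.py  thin `ssgasm` command
```

See `docs/methods.md` for the model, parameter defaults, and limitations.
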