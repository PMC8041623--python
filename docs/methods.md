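# Methods

## Model

The assembler treats short-read contigs as accurate but short, and long
reads as structurally informative but noisy. Rather than correcting or
overlapping the long reads, it converts each read into synthetic mate
pairs — 250-bp forward–reverse mates cut at fixed inserts, stepped every
150 bp — and scaffolds the contigs with them. Because every synthetic pair
remembers its read of origin, sets of mate edges that are mutually
consistent in length and share read labels are evidence of a long-read
overlap, recovered by graph reduction instead of alignment. The gap
sequence between ordered contigs is rebuilt from the labeled reads
themselves and finally polished with the contigs left out of the backbone.

Assumptions: short-read contigs are locally accurate (no base polishing of
contig interiors is ever attempted — contig bases are never rewritten);
long reads are long enough to span inter-contig gaps (gaps larger than the
largest usable insert remain N gaps or line breaks); coverage is roughly
uniform so that contig coverage separates single-copy from repeat
sequence.

## Stages and parameters

**Pseudo-alignment.** Canonical k-mers are hashed with an invertible
64-bit mix (SplitMix64 finalizer) — deterministic and seedless — and
(w,k)-minimizers are chained per (target, strand) by longest strictly
increasing subsequence over target positions. Presets: `shortr` (10,21),
reject pairs with mapq ≤ 30 or coverage ≤ 50%; `ontlon`/`ontraw`/`pacraw`/
`pacccs` (5,20), 250-bp mates, reject at mapq ≤ 40 or coverage ≤ 65%;
`pacraw` homopolymer-compresses before sketching (raw PacBio's dominant
indel mode), `pacccs` shares the geometry without compression. Mapping
quality is `round(60·(1 − s2/s1))` over the best and second-best chain
scores — the engine this mirrors publishes only the monotonicity of its
score, not a formula, so the ratio form is this package's choice; the
within-target secondary chain (tandem copies) is found by re-chaining
outside the primary chain's span. Minimizers occurring > 500 times in an
index are skipped during queries (production minimizer engines apply a
similar frequency cut; the bound keeps chaining near-linear). Alignments also
report the chained-anchor footprint (`aln_start`, `aln_end`), the
soft-clip-equivalent interval used wherever an interval must not extend
past where matching stops.

**Spectrum.** 24 inserts from 0.5 to 200 kb (dense to 10 kb, decade steps
above; extended to 300/400/500 kb when the read N50 is ≥ 100 kb); presets
other than ultralong truncate at twice the read N50. The interior spacing
of the schedule is this package's concretization — the count (24) and the
range are the contract. Per-library σ = max(50 bp, 0.10·insert): long-read
indels perturb the genomic distance between mates roughly proportionally
to the insert, and 10% is a conservative bound for ≤ 15% error reads; it
is exposed in `Spectrum` and is the most likely knob to tune against real
data. Same-contig synthetic pairs are absorbed as contig labels and do not
currently re-estimate per-library σ.

**Contig QC.** Insert mean/sd come from strictly filtered proper pairs
(distances > 10× the median discarded; ≥ 100 pairs required). Physical
fragments are pairs mapped within one contig at proper orientation with
length in [x̄ − 2.5σ, x̄ + 2.5σ]. Fragments and base coverage use each
mate's best placement regardless of mapping quality: ambiguity *between
repeat copies on other contigs* says nothing about the host contig's
integrity, while a true chimeric junction has no proper-distance spanning
pair under any placement — so detection is unaffected and intact repeat
interiors are not punctured by false coverage holes. Fragment endpoints
use the chained footprint so a junction-straddling mate cannot bridge the
dip with its unaligned tail. Runs below depth 7 become LQIs (internal /
start / end / whole); runs lying entirely within one mean insert length of
a contig terminus are tolerated (termini cannot accrue full physical
coverage) unless coverage is zero for longer than that. Contigs are split
at internal LQIs, trimmed at terminal ones, dropped when whole; parts
shorter than 2k (42 bp) are discarded.

**SSG.** Orientation frame: each mate designates the contig end its
fragment exits (forward mate → head, reverse → tail; mirrored for the
reverse-complemented mate 2), and the formula's `l(C) − pos` terms are the
fragment overhangs measured from that end. This frame is verified by a
round-trip test on adjacent contigs with a known gap. Bundled lengths are
floored at −min(l(Cᵢ), l(Cⱼ)) to keep path arithmetic finite.

**Reduction.** Repeat masking: ū = mean coverage of the longest 10% of
contigs; coverage > 1.5·ū masks. The coherent-path DFS runs inside
biconnected components of the unmasked graph, prunes at 80 path vertices
or when the partial path is already too long, requires the reduced edge's
label set to be a (non-strict) subset of every path edge's labels —
strict subsetting would forbid reducing onto edges labeled by exactly the
same reads, contradicting the intended minimal example — and among
complete paths keeps the one with the most synthetic-pair hits from the
edge's own reads; for edges ≥ 100 kb the search stops after 100 complete
paths. Child order is ascending bundled length with lexicographic
tie-break (determinism). Weight transfer adds w(e) to *every* path mate
edge, so the total mate-edge weight grows by (k−1)·w(e) per reduction —
an exact bookkeeping identity the tests assert; label sets are *not*
merged on reduction (weights only).

**Backbone.** The matching over eligible mate edges (weight ≥ 5, no
repeat contacts) is computed exactly with Edmonds' blossom algorithm —
the original approximation's 2/3 worst-case guarantee is thereby
trivially met, and a greedy take-if-free variant remains available behind
a flag for scale experiments. Cycles (rare) are destroyed at their
lowest-weight mate edge, ties by edge id. Validation converts contig
edges, mate edges spanned by a ≥ 20 kb read, and reduced edges whose
line-projected length matches within 4·max(σ) into physical fragments;
a join with zero coverage is split when fewer than 4 reads support it
("support < mlr" — the threshold's own boundary is read as: exactly 4
supporting reads keep the join).

**Consensus and gap filling.** Reads per edge are ranked by contributed
synthetic-pair count (ties by id); the top contributor is the template and
up to N = 20 are used. Each other read is strand-oriented to the template
and globally located in it by edlib (Myers bit-vector); alignments are cut
at template window boundaries (w = 500 bp) and chunks below 65% identity
are dropped per window — the identity filter is applied per chunk, not
globally, because a read may be good over one window and clipped in
another. The consensus is the heaviest path through a template-anchored
alignment graph: template bases form the backbone, chunks vote for
substitutions, deletions and insertions, and because votes are anchored to
template columns the heaviest path factorizes into per-column weighted
majority (insertions are emitted when a majority of covering chunks agree
on one). Windows with no surviving chunk pass the template through.
Contig-end anchors (2 kb, ≥ 80% identity, both strands tried) place the
fill boundaries; overlapping anchors merge the contigs at the implied
overlap; a failed anchor leaves l(e) N's, flagged. The per-template-base
depth of surviving chunks is retained as the consensus depth.

**Polishing.** The graph polisher repeats the coherent-path search per
filled edge with backbone contigs masked (so paths run through repeat and
singleton contigs), capped at 5·10⁶ DFS edge extensions per edge —
"iterations" are edge extensions, the natural unit of that search. A path
contig is spliced into the consensus when its identity reaches the
depth-scaled expectation — linear from 80% at depth 1 to 99% at depth 20
(the stated endpoints; the interpolation is this package's choice) — and
the alignment covers ≥ 75% of the contig (match/mismatch columns over
contig length). The alignment polisher indexes the consensi with
(5,17)-minimizers (frequency > 1000 excluded), chains singleton contigs
against them, lays hits out greedily by anchor count without overlap, and
splices by the same rule. A contig is marked used at its first splice.
Output: lines (descending length, ids `ssg-L<n>`) plus unused contigs
> 5 kb.

## The simulator, and what passing tests do not show

`simdata` emulates: uniform-random genomes with planted, substitution-
diverged repeat families; log-normal long-read lengths (truncated below,
heavy-tailed like Nanopore length profiles) with independent per-base
substitutions and indels and an optional homopolymer indel bias;
error-free short pairs with Normal inserts (accurate short reads are an
input assumption, and it is contig structure, not short-read error, that
downstream stages exercise); and draft contigs made by fragmenting the
genome, optionally concatenating distant fragments into chimeras
(junctions ≥ 50 kb apart so physical-coverage detection is well-posed at
toy scale) and withholding a fraction of internal fragments — the missing
regions a real short-read assembler fails to assemble, which is what
gives gap lengths their spread. It does **not** model: diploid
heterozygosity, collapsed repeats in the draft (simulated contigs carry
every repeat copy, so repeat masking rarely fires and the polishers are
exercised mainly by constructed fixtures), context-dependent or
signal-level error profiles, chimeric long reads, or coverage bias.
Passing tests therefore demonstrate algorithmic correctness and
end-to-end behavior under idealized error models, not performance on real
basecalls.

The standard demonstration conditions (`demo_simulation`): 1-Mb genome,
two 2-kb repeat families at 2% divergence (three copies each), 30× long
reads of mean 15 kb with 5% total error (2% substitutions, 1.5% + 1.5%
indels), 50× 2×150 pairs at 350 ± 20 bp, 250 draft breaks with 25% of
internal fragments withheld. At this scale a run produces ~150 filled
gaps spanning ~0.05–10 kb and finishes in minutes on one CPU; the same
code paths scale to larger genomes linearly in read bases.

## Numerical and degenerate-input choices

0-based half-open coordinates everywhere; 1-based only in SAM emission.
Strand ties in canonical k-mers resolve to forward. Chain ties resolve by
the composite sort key (target, strand, query position, target position).
Consensus base ties resolve base-over-deletion, then lexicographically.
Empty sequences: parsers yield them; the aligner returns unmapped for
reads shorter than k; reads shorter than the smallest insert contribute no
pairs. An assembly with no accepted pairs degrades to one line per contig.

## Known limitations

- The per-library σ rule (10%) is a stand-in for the unpublished value;
  bundled σ, reduction tolerances and validation windows inherit it.
- The pipeline maps synthetic mates by slicing the whole read's minimizer
  set to each mate window; extracting each 250-bp mate separately (the
  per-pair API) selects minimizers slightly differently at window
  boundaries. Both routes are exposed and tested; the pipeline uses the
  batch route for speed.
- Validation, matching and polishing operate per connected structure in
  memory; no external-memory paths are implemented (the read database is
  an in-memory store with the prescribed global mate-edge ordering).
- Consensus quality saturates around Q30 at depth ~20 under the 5% error
  model; short-read base polishing of gap interiors is out of scope.
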