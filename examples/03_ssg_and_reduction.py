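"""Build a synthetic scaffolding graph and transitively reduce it.

Three contigs in a row, one error-free long read spanning them, two
insert-size libraries: the long-range mate edge is reduced onto the path
of short-range edges, transferring its weight — an implicit long-read
overlap computed without any read-vs-read alignment.
"""

import ssgasm as S
from ssgasm.minimizer_align import PRESETS
from ssgasm.synthetic_pairs import Spectrum

genome = S.simulate_genome(40_000, seed=5)
chrom = genome.chromosomes[0]
contigs = [
    S.SeqRecord("A", chrom[2_000:10_000]),
    S.SeqRecord("B", chrom[10_400:18_000]),
    S.SeqRecord("C", chrom[18_300:26_000]),
]
read = S.SeqRecord("lr0", chrom[4_000:24_000])  # spans all three contigs
spectrum = Spectrum(((3000, 300.0), (12_000, 1200.0)))

idx = S.build_index(contigs, PRESETS["ontraw"])
accepted = []
for p in S.extract_synthetic_pairs(read, spectrum):
    a1, a2, ok = S.map_pair(
        S.SeqRecord("m1", p.mate1), S.SeqRecord("m2", p.mate2),
        idx, PRESETS["ontraw"],
    )
    if ok:
        accepted.append((a1, a2, p.library, p.read_id, p.offset))

g = S.build_ssg(contigs, accepted, spectrum, {c.id: 30.0 for c in contigs})
print(f"accepted pairs: {len(accepted)}, bundled mate edges: {len(g.mate_edges)}")
for e in g.mate_edges.values():
    print(f"  {e.u}--{e.v}  l={e.l:8.1f}  sigma={e.sigma:6.1f}  w={e.w}")

db = S.transitive_reduce(g)
print(f"reduced {len(db)} long-range edge(s); weights after transfer:")
for e in g.active_mate_edges():
    print(f"  {e.u}--{e.v}  w={e.w}")
print("The A--C edge vanished and its weight moved onto A--B and B--C:")
print("those two joins are now supported by both direct and long-range evidence.")
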