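"""Detect and split chimeric draft contigs with short-read pairs.

Fragments a 150-kb genome, glues two distant fragments into chimeras,
maps 50x short pairs back, and shows where physical coverage exposes the
false junctions.
"""

import ssgasm as S
from ssgasm.minimizer_align import PRESETS
from ssgasm.pipeline import PipelineConfig, _correct_contigs_stage, _map_short_pairs

genome = S.simulate_genome(150_000, seed=21)
contigs, truth = S.make_draft_contigs(genome, n_breaks=25, n_chimeras=2, seed=22)
pairs = S.simulate_short_pairs(genome, coverage=50, seed=23)

distances, frags, basecov = _map_short_pairs(pairs, contigs, PRESETS["shortr"])
corrected, coverage, report = _correct_contigs_stage(
    contigs, distances, frags, basecov, PipelineConfig()
)

print(f"{len(contigs)} draft contigs -> {len(corrected)} after correction")
for cid, junction in truth.chimera_junctions.items():
    calls = [r for r in report if r[0] == cid]
    for _, start, end, kind, action in calls:
        off = abs((start + end) / 2 - junction)
        print(f"  {cid}: true junction {junction}, {kind} LQI "
              f"[{start},{end}) -> {action} ({off:.0f} bp off)")
print("Each chimera should be split within ~1 kb of its recorded junction;")
print("chimera-free contigs pass through untouched.")
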