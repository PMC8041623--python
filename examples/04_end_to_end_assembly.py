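"""Assemble a 200-kb simulation end to end and check it against truth.

Runs the full pipeline (QC, SSG, reduction, matching, validation, gap
filling, polishing) and reports contiguity, the estimated-vs-realized
gap-length agreement, and identity to the simulated genome.
"""

import re

import edlib
import numpy as np

import ssgasm as S
from ssgasm.pipeline import PipelineConfig, n50, run_pipeline

genome = S.simulate_genome(
    200_000, n_repeat_families=2, repeat_len=2000,
    copies_per_family=3, divergence=0.02, seed=1,
)
em = S.ErrorModel(sub_rate=0.02, ins_rate=0.015, del_rate=0.015)
reads, _ = S.simulate_long_reads(genome, coverage=25, length_mean=10_000, em=em, seed=2)
pairs = list(S.simulate_short_pairs(genome, coverage=40, seed=3))
contigs, _ = S.make_draft_contigs(genome, n_breaks=60, seed=4, drop_frac=0.2)

res = run_pipeline(
    contigs, pairs, reads, PipelineConfig(preset="ontraw"), genome_size=genome.length
)

draft = n50([len(c.seq) for c in contigs], genome.length)
print(f"draft NG50 {draft} bp -> assembly NG50 {int(res.metrics['ng50'])} bp "
      f"({res.metrics['ng50'] / draft:.0f}x gain)")

fills = [f for f in res.fills.fills if f.realized is not None]
est = np.array([f.l_e for f in fills])
real = np.array([f.realized for f in fills])
r2 = np.corrcoef(est, real)[0, 1] ** 2
print(f"gap fills: {len(fills)}; estimated vs realized length R^2 = {r2:.4f}")

chrom = genome.chromosomes[0]
rc = str.maketrans("ACGTN", "TGCAN")
tb = td = 0
for rec in res.assembly:
    for block in re.split("N+", rec.seq):
        if len(block) < 200:
            continue
        d = min(
            edlib.align(block, chrom, mode="HW")["editDistance"],
            edlib.align(block[::-1].translate(rc), chrom, mode="HW")["editDistance"],
        )
        tb += len(block)
        td += d
print(f"identity to truth over aligned blocks: {1 - td / tb:.5f}")
print("R^2 near 1 means the SSG's length estimates predict the sequence")
print("actually spliced in; identity ~0.999+ shows consensus gap filling")
print("recovers the withheld genome regions from 5%-error reads.")
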