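"""Shared fixtures: small simulated datasets with ground truth."""

import pytest

import ssgasm as S
from ssgasm.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def unique_genome():
    """50-kb repeat-free genome."""
    return S.simulate_genome(50_000, seed=11)


@pytest.fixture(scope="session")
def repeat_genome():
    """120-kb genome with two diverged 2-kb repeat families."""
    return S.simulate_genome(
        120_000,
        n_repeat_families=2,
        repeat_len=2000,
        copies_per_family=3,
        divergence=0.02,
        seed=13,
    )


@pytest.fixture(scope="session")
def small_assembly():
    """A complete 200-kb assembly run with truth, shared across tests."""
    g = S.simulate_genome(
        200_000,
        n_repeat_families=2,
        repeat_len=2000,
        copies_per_family=3,
        divergence=0.02,
        seed=1,
    )
    em = S.ErrorModel(sub_rate=0.02, ins_rate=0.015, del_rate=0.015)
    reads, read_truth = S.simulate_long_reads(
        g, coverage=25, length_mean=10000, em=em, seed=2
    )
    pairs = list(S.simulate_short_pairs(g, coverage=40, seed=3))
    contigs, draft_truth = S.make_draft_contigs(
        g, n_breaks=60, seed=4, drop_frac=0.2
    )
    res = run_pipeline(
        contigs,
        pairs,
        reads,
        PipelineConfig(preset="ontraw", seed=1),
        genome_size=g.length,
    )
    return {
        "genome": g,
        "reads": reads,
        "read_truth": read_truth,
        "pairs": pairs,
        "contigs": contigs,
        "draft_truth": draft_truth,
        "result": res,
    }
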