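"""Shared fixtures: tiny deterministic genomes and cohorts."""

import numpy as np
import pandas as pd
import pytest

from pmdkit import CohortConfig, GenomeSequence, simulate_cohort, simulate_genome


@pytest.fixture
def toy_genome():
    """Hand-written sequences exercising CpG / WCGW edge cases."""
    return GenomeSequence(
        {
            "chrA": "TACGTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTACGTT",
            "chrB": "CGCG",
        }
    )


@pytest.fixture(scope="session")
def small_cfg():
    return CohortConfig(
        seed=11,
        n_patients=4,
        chrom_sizes={"chr1": 1_000_000, "chr2": 1_000_000},
        n_genes=30,
        n_planted_dmrs=10,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    genome, truth = simulate_genome(small_cfg)
    return genome, truth


def random_intervals(rng, n, span=10_000, max_len=500, chroms=("c1", "c2")):
    """Random raw interval records for oracle tests."""
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(1, max_len))
        out.append((chrom, start, start + length))
    return out


def bitmask_of(records, span=10_000, chroms=("c1", "c2")):
    """Per-base boolean occupancy, the brute-force reference for interval math."""
    masks = {c: np.zeros(span, dtype=bool) for c in chroms}
    for chrom, s, e in records:
        masks[chrom][s:e] = True
    return masks
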