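import numpy as np
import pandas as pd
import pytest

from svdomest.simulate import (
    SimulationConfig,
    plan_truth,
    simulate_genome_pair,
    simulate_population_genotypes,
)


@pytest.fixture(scope="session")
def toy_genomes():
    """Small genome pair with a mix of planted SV types."""
    config = SimulationConfig(
        seed=11,
        n_chromosomes=1,
        chrom_length=200_000,
        n_deletions=8,
        n_insertions=8,
        n_inversions=2,
        sv_size_range=(100, 2_000),
        snp_rate=1e-4,
    )
    genome_a, genome_b, truth = simulate_genome_pair(config)
    return config, genome_a, genome_b, truth


@pytest.fixture(scope="session")
def small_population():
    """Population genotype matrix with positions, for popgen tests."""
    config = SimulationConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length=5_000_000,
        n_deletions=120,
        n_insertions=115,
        n_inversions=5,
        group_sizes=(30, 60, 60, 30),
        missing_rate=0.05,
    )
    truth = plan_truth(config)
    matrix = simulate_population_genotypes(truth, config)
    return config, truth, matrix
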