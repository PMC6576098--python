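"""Shared fixtures: one small simulated study reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import tetrasnp as t
from tetrasnp.core import GenotypeMatrix


@pytest.fixture(scope="session")
def small_config():
    return t.SimulationConfig(seed=11, n_loci=800, n_chromosomes=3,
                              chrom_length_bp=600_000, n_diversity_a=16,
                              n_groups_species_a=4, n_tetraploids=6,
                              n_species_b=4, missing_rate=0.05)


@pytest.fixture(scope="session")
def sim(small_config):
    """Model, catalog, pools, diversity matrix and panel for one config."""
    model = t.simulate.simulate_genome_model(small_config)
    catalog = t.simulate.simulate_loci(model, small_config)
    pools, matrix, panel = t.simulate.simulate_progenitor_panels(
        model, small_config)
    return dict(config=small_config, model=model, catalog=catalog,
                pools=pools, matrix=matrix, panel=panel)


def random_matrix(rng, n_loci, n_samples, missing_rate=0.1):
    """Random dosage matrix helper used by several oracle tests."""
    calls = rng.integers(0, 3, size=(n_loci, n_samples)).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate] = t.MISSING
    return GenotypeMatrix(
        calls,
        np.asarray([f"L{i}" for i in range(n_loci)], dtype=object),
        np.asarray([f"S{j}" for j in range(n_samples)], dtype=object))
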