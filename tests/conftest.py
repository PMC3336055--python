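import numpy as np
import pytest

import mitekit as mk
from mitekit import synthetic as syn


@pytest.fixture(scope="session")
def families6():
    return mk.simulate_families(6, seed=11)


@pytest.fixture(scope="session")
def small_sim(families6):
    """A compact genome with 60 planted insertions and known truth."""
    cfg = syn.SimulationConfig(seed=11, n_insertions=60, genome_length=70_000)
    genome, truth = syn.simulate_genome_with_insertions(cfg, families6)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def clean_sim(families6):
    """Zero-mutation simulation: every insertion a perfect family copy."""
    cfg = syn.SimulationConfig(
        seed=13, n_insertions=60, genome_length=70_000, fraction_perfect_tsd=1.0, mismatch_load=0.0
    )
    genome, truth = syn.simulate_genome_with_insertions(cfg, families6)
    return cfg, genome, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
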