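import numpy as np
import pytest

from nucphase import nucleosome as nuc
from nucphase.synthetic import SimConfig, simulate_genome, simulate_mnase


@pytest.fixture(scope="session")
def sim():
    """Default simulated study: genome, annotation, and ground truth."""
    config = SimConfig()
    genome, genes, truth = simulate_genome(config)
    return config, genome, genes, truth


@pytest.fixture(scope="session")
def wt_fragments(sim):
    config, genome, _genes, truth = sim
    return simulate_mnase(genome, truth, "wt", 50_000, config)


@pytest.fixture(scope="session")
def wt_density(sim, wt_fragments):
    _config, genome, _genes, _truth = sim
    return nuc.midpoint_density(wt_fragments, genome)


@pytest.fixture(scope="session")
def wt_dyads(wt_density):
    return nuc.call_dyads(wt_density)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
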