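import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True)
settings.load_profile("stable")

from glshet.panels import genotype_means
from glshet.simulate import (
    SimulationConfig,
    noise_free,
    simulate_concentrations,
    simulate_pedigree,
)


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def pedigree(config):
    return simulate_pedigree(config)


@pytest.fixture(scope="session")
def panel_and_truth(config, pedigree):
    return simulate_concentrations(config, pedigree)


@pytest.fixture(scope="session")
def panel(panel_and_truth):
    return panel_and_truth[0]


@pytest.fixture(scope="session")
def truth(panel_and_truth):
    return panel_and_truth[1]


@pytest.fixture(scope="session")
def means(panel):
    return genotype_means(panel).mean


@pytest.fixture(scope="session")
def noise_free_panel(config, pedigree):
    panel, truth = simulate_concentrations(noise_free(config), pedigree)
    return panel, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_composition(rng, k):
    """Strictly positive random composition (unnormalised parts)."""
    return rng.gamma(shape=2.0, scale=1.0, size=k) + 1e-3
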