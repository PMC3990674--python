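import numpy as np
import pytest
from hypothesis import settings

from isoniche.mixing_model import MCMCSettings
from isoniche.synthetic_data import ScenarioConfig, generate_scenario

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A reduced study: two population-years, one tight and one spread."""
    return ScenarioConfig(
        population_years=(("Catalonia", 2009), ("Andalusia", 2011)),
        n_territories=(8, 6),
        tight_population_years=(("Andalusia", 2011),),
        seed=1234)


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return generate_scenario(small_config)


@pytest.fixture(scope="session")
def default_scenario():
    """The full default study shape (7 population-years, 130 territories)."""
    return generate_scenario(ScenarioConfig(), seed=99)


@pytest.fixture
def fast_mcmc():
    """Light chains for unit tests of the sampler plumbing."""
    return MCMCSettings(n_chains=2, burn_in=2000, n_samples=8000, thin=8,
                        seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20140417)
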