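import numpy as np
import pytest

from poolsim import ScenarioConfig, draw_gammas, simulate_individuals


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scenario():
    """A cheap scenario for unit tests: 40 features, 12 samples per class."""
    return ScenarioConfig(
        n_features=40, n_per_class=12, bio_variance=0.2, tech_variance=0.04,
        n_markers=4,
    )


@pytest.fixture
def small_dataset(small_scenario, rng):
    gammas = draw_gammas(small_scenario, rng)
    return simulate_individuals(small_scenario, gammas, rng)
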