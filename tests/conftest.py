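import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from panelcnv import SimulationConfig, simulate_coverage, simulate_panel


@pytest.fixture(scope="session")
def small_sim_config():
    return SimulationConfig(n_regions=300, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_sim_config):
    """A 300-region synthetic panel plus its catalog."""
    return simulate_panel(small_sim_config)


@pytest.fixture(scope="session")
def diploid_pool(small_panel, small_sim_config):
    """Coverage matrix of eight event-free samples on the small panel."""
    regions, catalog = small_panel
    events = {f"s{i}": [] for i in range(8)}
    matrix, _ = simulate_coverage(regions, small_sim_config, events, catalog)
    return matrix


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
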