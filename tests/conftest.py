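import numpy as np
import pytest

from nticell import EstimatorConfig, RegimeSpec, simulate_community, simulate_lineage


@pytest.fixture(scope="session")
def est_config():
    return EstimatorConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_coupled_bundle():
    """3-generation coupled community with short lifetimes (fast tests)."""
    lineage = simulate_lineage(3, 600, seed=11)
    return simulate_community(lineage, RegimeSpec.coupled(), seed=11)


@pytest.fixture(scope="session")
def small_ic_bundle():
    lineage = simulate_lineage(3, 600, seed=12)
    return simulate_community(lineage, RegimeSpec.information_closed(), seed=12)
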