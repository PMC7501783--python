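import numpy as np
import pytest

from splitmig import (
    SimulationConfig,
    SplitMigParams,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def truth_params():
    return SplitMigParams(nu1=2.0, nu2=4.0, T=0.5, m=0.5)


@pytest.fixture(scope="session")
def small_dataset(truth_params):
    """A 4+4 individual dataset, a few hundred variable loci."""
    return simulate_dataset(
        SimulationConfig(n1=4, n2=4, L=800, params=truth_params, seed=1234)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(77)
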