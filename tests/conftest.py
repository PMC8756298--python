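import numpy as np
import pytest

from spacelog import SimulationScenario, simulate_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ba_data():
    """A small BA dataset (m=15, n=200) shared across tests."""
    scenario = SimulationScenario(model="BA", m=15, n=200, e=1, seed=7)
    return simulate_scenario(scenario, graph_seed=7, data_seed=1000007)


def random_gaussian_matrix(rng, n, m, correlated=True):
    """Generic test input: centered Gaussian data, optionally correlated."""
    if not correlated:
        return rng.standard_normal((n, m))
    a = rng.standard_normal((m, m)) / np.sqrt(m)
    cov = np.eye(m) + a @ a.T
    chol = np.linalg.cholesky(cov)
    return rng.standard_normal((n, m)) @ chol.T
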