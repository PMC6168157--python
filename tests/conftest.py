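import numpy as np
import pytest

from hscpolarity.model_core import OdeParams
from hscpolarity.synthetic import ScenarioConfig, default_genome


@pytest.fixture(scope="session")
def params():
    """Default bistable parameterization (fixed points 1, 2, 4)."""
    return OdeParams()


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scenario():
    """Scenario sized for fast unit tests."""
    return ScenarioConfig(
        master_seed=11, n_imaging_pairs=100, n_transplant_pairs=40,
        n_genes=400, n_expression_pairs=6, n_atac_pairs=4,
        n_centroids=120, pairs_per_condition=500)
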