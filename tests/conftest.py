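import numpy as np
import pytest
from hypothesis import settings

from arraysim import ModelParams, simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """One default simulation (10,000 genes, 7 vs 7), shared read-only."""
    return simulate(ModelParams())


@pytest.fixture
def small_params():
    return ModelParams(n=200, m1=4, m2=4, rseed=7)
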