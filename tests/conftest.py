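import numpy as np
import pytest

from ichthyospec import ModelConfig, SizeGrid, ToothAxis
from ichthyospec.simulate import DEFAULT_THETA


@pytest.fixture(scope="session")
def theta_true():
    return DEFAULT_THETA


@pytest.fixture(scope="session")
def default_config():
    return ModelConfig()


@pytest.fixture(scope="session")
def tooth_axis():
    return ToothAxis()


@pytest.fixture(scope="session")
def small_grid():
    return SizeGrid.logarithmic(n_bins=24)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
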