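import numpy as np
import pytest

from pelthg.error_surface import ConversionModel
from pelthg.synthetic_pelts import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def dataset(default_config):
    """One full synthetic study (8 grids, 16 organ records)."""
    return simulate_dataset(default_config)


@pytest.fixture(scope="session")
def grids(dataset):
    return dataset[0]


@pytest.fixture(scope="session")
def organs(dataset):
    return dataset[1]


@pytest.fixture(scope="session")
def placeholder_model():
    return ConversionModel.placeholder()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
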