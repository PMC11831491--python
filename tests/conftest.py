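import numpy as np
import pytest

from nanosolder.dataset import SimConfig, build_dataset, ParamGrid
from nanosolder.spectra import (
    celsius_to_kelvin,
    synthesize_emission_database,
)


@pytest.fixture(scope="session")
def default_db():
    """Shipped six-node (30-80 degC) synthetic emission database."""
    return synthesize_emission_database()


@pytest.fixture(scope="session")
def wide_db():
    """Extended-range database used for field rendering and the plant."""
    return synthesize_emission_database(
        temperatures_K=celsius_to_kelvin(np.arange(15.0, 120.0 + 1e-9, 5.0))
    )


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """A small rendered+filtered dataset shared by training_data/upscaler tests."""
    samples, manifest = build_dataset(n=80, seed=7)
    return samples, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
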