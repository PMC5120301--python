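import numpy as np
import pytest

from thalcort import ModelParameters, SimulationConfig


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Reference parameter set at the (k4, k10) = (1, 3) operating point."""
    return ModelParameters()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20160101)


@pytest.fixture()
def short_config() -> SimulationConfig:
    return SimulationConfig(duration=2.0, transient_discard=0.5)
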