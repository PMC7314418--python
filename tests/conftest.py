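import numpy as np
import pytest

from vdac import SimulationConfig
from vdac.containers import NoiseModel, Seeds


@pytest.fixture()
def small_config() -> SimulationConfig:
    """Cheap 16-channel configuration for unit-level simulations."""
    return SimulationConfig(
        n_participants=4,
        n_channels=16,
        epoch_window_ms=(-100.0, 500.0),
    )


@pytest.fixture()
def noiseless_config() -> SimulationConfig:
    """Noise-free configuration: planted signals are exactly recoverable."""
    return SimulationConfig(
        n_participants=4,
        n_channels=16,
        epoch_window_ms=(-100.0, 500.0),
        noise_model=NoiseModel(spatial_rank=4, ar1_coef=0.9, noise_sd=0.0),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
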