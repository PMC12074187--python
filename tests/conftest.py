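import warnings

import numpy as np
import pytest

from cvrarima.synthetic import SimulationConfig, simulate_waveforms

# statsmodels emits convergence/frequency warnings for deliberately
# mis-specified grid cells; they are part of normal grid operation.
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def passive_config():
    """Fully pressure-passive patient (g = +1) with near-zero noise."""
    return SimulationConfig(
        seed=3, duration_min=60, autoregulation_gain=1.0,
        noise_sd={"ABP": 0.05, "ICP": 0.02, "rSO2": 0.1, "PbtO2": 0.1},
    )


@pytest.fixture(scope="session")
def passive_record(passive_config):
    return simulate_waveforms(passive_config)
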