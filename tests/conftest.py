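import numpy as np
import pytest

from ahpburst.biophys import Protocol, base_config, simulate_current_clamp
from ahpburst.synth import GeneratorParams, generate_cell_recording


@pytest.fixture(scope="session")
def quick_params():
    """Small synthetic cell used across detection/feature tests."""
    return GeneratorParams(n_bursts=5, seed=42)


@pytest.fixture(scope="session")
def quick_cell(quick_params):
    return generate_cell_recording(quick_params)


@pytest.fixture(scope="session")
def base_model():
    return base_config()


@pytest.fixture(scope="session")
def sim_single_spike(base_model):
    """One 400 pA / 3 ms evoked spike from rest, with 50 ms tail."""
    proto = Protocol.current_steps((0.0, 300.0), (400.0, 3.0), (0.0, 50.0))
    return simulate_current_clamp(base_model, proto)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
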