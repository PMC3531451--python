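import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from mdgel.simulate import SimulationConfig, simulate_scene  # noqa: E402


@pytest.fixture(scope="session")
def benchmark_scene():
    """The default 300-spot benchmark scene at a fixed seed."""
    return simulate_scene(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig(seed=7, noise_sd=0.0, background_level=0.0)


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_config):
    return simulate_scene(noiseless_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
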