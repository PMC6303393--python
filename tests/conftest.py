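import numpy as np
import pytest

from rdpattern import ModelParameters, SimulationConfig


@pytest.fixture
def params():
    """Default measured/estimated parameter set."""
    return ModelParameters()


@pytest.fixture
def turing_point_params(params):
    """(alpha_N, alpha_L) = (0.8, 4.0): the reference Turing-unstable point."""
    return params.replace(alpha_N=0.8, alpha_L=4.0)


@pytest.fixture
def fast_config():
    """A short 1D run for integration-behavior tests (not for outcomes)."""
    return SimulationConfig(domain_length=500.0, dx=10.0, dt=0.4, duration=400.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
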