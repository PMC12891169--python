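import numpy as np
import pytest

from lsoloop import CantileverParams, NeuralParams


@pytest.fixture(scope="session")
def sensor_params() -> CantileverParams:
    """Reference cantilever parameter set."""
    return CantileverParams()


@pytest.fixture(scope="session")
def neural_closed() -> NeuralParams:
    """Closed-loop weights at excitation-inhibition balance 1/2."""
    return NeuralParams(w_mntb_exc=200.0, w_lso_exc=100.0)


@pytest.fixture(scope="session")
def neural_open() -> NeuralParams:
    """Weights for the table-driven open-loop mode."""
    return NeuralParams(w_mntb_exc=2.0, w_lso_exc=1.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
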