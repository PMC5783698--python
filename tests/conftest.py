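import numpy as np
import pytest

from nfkb_modehop import (ModelParameters, TNFSignal, integrate_rk4,
                          default_parameters)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return default_parameters()


@pytest.fixture(scope="session")
def free_running_trajectory(params):
    """Constant-TNF deterministic run shared across tests (3000 min)."""
    return integrate_rk4(None, params, TNFSignal.constant(), t_end=3000.0)


@pytest.fixture(scope="session")
def entrained_trajectory(params):
    """A 1:2-locked run (T=180 min, A=0.15) past its slow transient."""
    sig = TNFSignal(period=180.0, amplitude=0.15)
    return integrate_rk4(None, params, sig, t_end=20000.0).after(14000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20160912)
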