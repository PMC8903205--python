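import numpy as np
import pytest

from larynxsim.config import SimConfig, DEFAULT_CONFIG
from larynxsim.tissue import load_layer_params


@pytest.fixture(scope="session")
def layers():
    return load_layer_params()


@pytest.fixture(scope="session")
def cfg():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def coarse_sweep():
    """One shared 25%-step activation sweep (the expensive fixture).

    Several map-level properties are checked against this single run.
    """
    from larynxsim.sweep import run_sweep
    return run_sweep(25)
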