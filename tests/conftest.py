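import numpy as np
import pytest

from preflex import ModelParams, StimProtocol
from preflex.engine import pin_reference_touchdown
from preflex.fixtures import make_mini_config


@pytest.fixture(scope="session")
def params():
    """Default (calibrated) full-resolution parameter set."""
    return ModelParams()


@pytest.fixture(scope="session")
def mini_params():
    """Coarse solver settings for fast end-to-end runs."""
    return make_mini_config(ModelParams())


@pytest.fixture(scope="session")
def pinned_params():
    """Defaults with the reference touch-down state re-pinned exactly."""
    return pin_reference_touchdown(ModelParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(20230320)


@pytest.fixture()
def const_protocol():
    return StimProtocol(kind="const")


@pytest.fixture()
def rising_protocol():
    return StimProtocol(kind="rising", t_td_expected=0.15)
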