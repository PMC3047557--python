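import numpy as np
import pytest

from sensillum.parameters import ParameterSet


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    """Bundled Antheraea parameterization (base + derived + channels)."""
    return ParameterSet.default()


@pytest.fixture(scope="session")
def scale40(params):
    return params.scale(40)


@pytest.fixture(scope="session")
def scale1(params):
    return params.scale(1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
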