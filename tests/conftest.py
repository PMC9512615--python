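import numpy as np
import pytest

from ctdenoise import generate_shepp_logan


@pytest.fixture(scope="session")
def phantom256():
    return generate_shepp_logan(256)


@pytest.fixture(scope="session")
def phantom512():
    return generate_shepp_logan(512)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
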