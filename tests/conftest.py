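import numpy as np
import pytest

from payoffmemory import build_donation_game, build_snowdrift_game


@pytest.fixture
def donation():
    return build_donation_game(3.0, 1.0)


@pytest.fixture
def donation_high():
    return build_donation_game(10.0, 1.0)


@pytest.fixture
def snowdrift():
    return build_snowdrift_game(3.0, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240619)
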