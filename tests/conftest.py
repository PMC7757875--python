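import numpy as np
import pytest

from coopgene.pgg import ContingentSchedule


@pytest.fixture(scope="session")
def identity_schedule():
    return ContingentSchedule(tuple(range(21)))


@pytest.fixture(scope="session")
def tent_schedule():
    # rises 0..10, falls back to 0: the canonical hump shape
    return ContingentSchedule(tuple(list(range(11)) + [20 - x for x in range(11, 21)]))


@pytest.fixture(scope="session")
def zeros_schedule():
    return ContingentSchedule((0,) * 21)


@pytest.fixture(scope="session")
def constant20_schedule():
    return ContingentSchedule((20,) * 21)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
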