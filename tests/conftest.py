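import numpy as np
import pytest

from symperc import stimuli


@pytest.fixture(scope="session")
def small_library():
    """4-part library on a 64-px canvas (fast)."""
    return stimuli.make_part_library(4, canvas=64, seed=11)


@pytest.fixture(scope="session")
def small_set(small_library):
    return stimuli.compose_two_part_objects(small_library)


@pytest.fixture(scope="session")
def seven_part_library():
    """The full-scale 7-part library on the default 140-px canvas."""
    return stimuli.make_part_library(7, canvas=140, seed=1)


@pytest.fixture(scope="session")
def seven_part_set(seven_part_library):
    return stimuli.compose_two_part_objects(seven_part_library)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
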