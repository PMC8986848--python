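import numpy as np
import pytest

from sscall.regions import Interval, Panel
from sscall.simulate import default_panel, make_reference


@pytest.fixture(scope="session")
def reference():
    return make_reference({"chr1": 2000}, seed=11)


@pytest.fixture(scope="session")
def panel(reference):
    return default_panel(reference, 300)


@pytest.fixture(scope="session")
def small_reference():
    return make_reference({"chrS": 400}, seed=5)


@pytest.fixture(scope="session")
def small_panel(small_reference):
    return Panel([Interval("chrS", 100, 160)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
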