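import numpy as np
import pytest

from guideselect import demo_library_spec


@pytest.fixture(scope="session")
def spec21():
    return demo_library_spec(21)


@pytest.fixture(scope="session")
def spec31():
    return demo_library_spec(31)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
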