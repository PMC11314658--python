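import numpy as np
import pytest

from eegfnirs import OptodeGeometry, make_stroop_schedule


@pytest.fixture
def geometry():
    return OptodeGeometry()


@pytest.fixture
def schedule():
    return make_stroop_schedule(30, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
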