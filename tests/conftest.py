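import numpy as np
import pytest

from lwdclock.screen import MODEL_II, screen_variant
from lwdclock.synthetic import ARCHIVED_MODEL_II_SET, gen_screen_fixture


@pytest.fixture(scope="session")
def archived_set():
    return dict(ARCHIVED_MODEL_II_SET)


@pytest.fixture(scope="session")
def tiny_screen():
    """A fast screen around the archived oscillatory set (seconds, not minutes)."""
    ranges, criteria, _ = gen_screen_fixture(seed=0, half_width_decades=0.05)
    return screen_variant(MODEL_II, ranges, n=400, seed=0, criteria=criteria)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
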