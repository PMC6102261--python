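import numpy as np
import pytest

from smlmpipe import Window


@pytest.fixture
def window_10um() -> Window:
    return Window(0.0, 0.0, 10_000.0, 10_000.0)


@pytest.fixture
def window_small() -> Window:
    return Window(0.0, 0.0, 2_000.0, 2_000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
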