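import numpy as np
import pytest

from cardionano.core import PointPattern, Window


@pytest.fixture
def unit_square_corners() -> PointPattern:
    """The four corners of the unit square (the worked geometry example)."""
    return PointPattern(
        [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]], Window.square(1.0)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
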