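import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture
def symmetric_v():
    """The canonical symmetric V profile: right angle at the base."""
    from toothmarks.landmarks import compute_wall_landmarks

    poly = np.array([[0.0, 0.0], [0.5, -0.5], [1.0, 0.0]])
    return compute_wall_landmarks(poly, (0, 1, 2), specimen_id="V")
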