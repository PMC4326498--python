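import numpy as np
import pytest

from kdiff import LabeledPattern, SimulationConfig, Window
from kdiff.pointprocess import CASE, CONTROL


def csr_pattern(rng, n_case, n_control, side=1.0):
    """Binomial (completely spatially random) labeled pattern in a square."""
    n = n_case + n_control
    xy = rng.uniform(0.0, side, size=(n, 2))
    mark = np.array([CASE] * n_case + [CONTROL] * n_control, dtype=object)
    mark = rng.permutation(mark)
    return LabeledPattern(xy[:, 0], xy[:, 1], mark, Window(side))


@pytest.fixture
def rng():
    return np.random.default_rng(20150115)


@pytest.fixture(scope="session")
def reduced_config():
    """Default geometry shrunk proportionally to an expected 600 points."""
    return SimulationConfig().scaled_to_expected_n(600)
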