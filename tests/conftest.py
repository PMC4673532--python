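import numpy as np
import pytest

from dnmark.embedding import SlidingWindowSpec, sliding_window_moments
from dnmark.experiments import SIGMA_BIG, SIGMA_SMALL, detect_jump, fold_sweep


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def fold_big_pre():
    """Pre-transition segment of one big-noise fold sweep (seed 0)."""
    traj = fold_sweep(SIGMA_BIG, seed=0)
    j = detect_jump(traj)
    assert j is not None and j > 60
    return traj.states[:j, :]


@pytest.fixture(scope="session")
def fold_small_pre():
    """Pre-transition segment of one small-noise fold sweep (seed 1)."""
    traj = fold_sweep(SIGMA_SMALL, seed=1)
    j = detect_jump(traj)
    assert j is not None and j > 60
    return traj.states[:j, :]


@pytest.fixture(scope="session")
def fold_big_moments(fold_big_pre):
    return sliding_window_moments(fold_big_pre, SlidingWindowSpec(10, 1))


@pytest.fixture
def toy_window():
    """3 variables x 4 samples; rows 1 and 2 proportional, row 3 reversed."""
    return np.array([[1.0, 2.0, 3.0, 4.0],
                     [2.0, 4.0, 6.0, 8.0],
                     [4.0, 3.0, 2.0, 1.0]]).T  # (samples, variables)
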