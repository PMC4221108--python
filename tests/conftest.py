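import numpy as np
import pytest

from emdperiod.emd import TimeGrid
from emdperiod.periodicity import build_null


@pytest.fixture(scope="session")
def grid():
    return TimeGrid()  # 36 points, 25 min, 300-min period, lag 12


@pytest.fixture(scope="session")
def null(grid):
    # shared Monte-Carlo null; 1e5 reps keeps p-value noise well below
    # every tolerance asserted in the suite
    return build_null(grid, n_reps=100_000, seed=20240501)


@pytest.fixture()
def t36():
    return np.arange(36, dtype=float)
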