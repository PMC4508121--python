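import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from flocknet import BoundingBox, TrajectorySet, OccupancySequences


@pytest.fixture
def unit_square():
    return BoundingBox(0.0, 10.0, 0.0, 10.0)


@pytest.fixture
def small_ts():
    """3 animals, 5 times, positions inside [0, 10]^2."""
    rng = np.random.default_rng(42)
    pos = rng.uniform(0.5, 9.5, size=(5, 3, 2))
    return TrajectorySet(["a", "b", "c"], np.arange(5), pos)


@pytest.fixture
def uniform_points():
    rng = np.random.default_rng(7)
    return rng.uniform(0.0, 10.0, size=(1000, 2))


def make_occ(columns, n_cells):
    """Occupancy panel from per-animal index sequences (columns)."""
    return OccupancySequences(np.column_stack(columns), n_cells)


@pytest.fixture
def occ_pair_identical():
    seq = np.array([0, 1, 2, 1, 0, 2, 2])
    return make_occ([seq, seq], 3)
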