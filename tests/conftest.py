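import numpy as np
import pytest

from migcube.age_structures import AgeGrouping, GroupedMigrationTable
from migcube.splines import BasisSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_basis():
    """A coarse basis (l = 7) for small oracle instances."""
    return BasisSpec(knot_start=0, knot_end=30, knot_spacing=6.0, degree=2)


def random_contiguous_grouping(rng, omega=29, g_max=6, open_prob=0.0):
    """A random contiguous grouping of 0..omega into up to g_max groups."""
    g = int(rng.integers(2, g_max + 1))
    edges = np.sort(rng.choice(np.arange(1, omega + 1), size=g - 1, replace=False))
    starts = np.concatenate([[0], edges])
    widths = np.diff(np.concatenate([starts, [omega + 1]]))
    groups = list(zip(starts, widths))
    if open_prob and rng.random() < open_prob:
        a, _ = groups[-1]
        groups[-1] = (a, np.inf)
    return AgeGrouping(tuple(groups), omega=omega)


def random_total_table(rng, omega=29, n_max=3):
    """A random single-destination grouped table on 0..omega."""
    grouping = random_contiguous_grouping(rng, omega=omega)
    g = grouping.n_groups
    n = int(rng.integers(1, n_max + 1))
    N = rng.integers(500, 5000, size=g).astype(float)
    p = rng.uniform(0.02, 0.3, size=g)
    M = np.round(N * p)
    return GroupedMigrationTable(grouping, M[:, None], N, n)
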