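import numpy as np
import pytest

from edmix.cells import UnitCell


def random_valid_cell(rng: np.random.Generator) -> UnitCell:
    """A random plausible cell: sorted lengths 3-20 A, angles 70-110 deg."""
    while True:
        lengths = np.sort(rng.uniform(3.0, 20.0, 3))
        angles = rng.uniform(70.0, 110.0, 3)
        try:
            return UnitCell(*lengths, *angles)
        except Exception:
            continue


def mild_valid_cell(rng: np.random.Generator) -> UnitCell:
    """A random modestly-skewed cell (angles 80-100 deg).

    For such cells every basis transformation needed to reach the reduced
    cell has entries within {-2..2}, keeping the brute-force enumeration
    oracle exhaustive.
    """
    while True:
        lengths = np.sort(rng.uniform(3.0, 20.0, 3))
        angles = rng.uniform(80.0, 100.0, 3)
        try:
            return UnitCell(*lengths, *angles)
        except Exception:
            continue


def rebase(cell: UnitCell, rng: np.random.Generator, n_shears: int = 2) -> UnitCell:
    """The same lattice in a different (unimodular) basis."""
    from edmix.cells import MetricTensor, cell_to_metric, metric_to_cell

    s = np.eye(3, dtype=int)
    for _ in range(n_shears):
        i, j = rng.choice(3, 2, replace=False)
        m = np.eye(3, dtype=int)
        m[i, j] = int(rng.choice([-1, 1]))
        s = s @ m
    g = cell_to_metric(cell).matrix
    return metric_to_cell(MetricTensor(s.T @ g @ s))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def library():
    from edmix.synthetic import default_library

    return default_library()
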