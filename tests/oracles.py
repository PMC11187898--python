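"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the brute-force
lattice-reduction oracle enumerates integer basis transformations directly,
and the symmetry-orbit oracle applies hand-listed group operations.
"""

from __future__ import annotations

import functools

import numpy as np


@functools.lru_cache(maxsize=1)
def unimodular_matrices() -> np.ndarray:
    """All 3x3 integer matrices with entries in {-2..2} and determinant +-1."""
    r = np.arange(-2, 3)
    grids = np.meshgrid(*([r] * 9), indexing="ij")
    ms = np.stack([g.ravel() for g in grids], axis=1).astype(np.int64).reshape(-1, 3, 3)
    a = ms
    det = (
        a[:, 0, 0] * (a[:, 1, 1] * a[:, 2, 2] - a[:, 1, 2] * a[:, 2, 1])
        - a[:, 0, 1] * (a[:, 1, 0] * a[:, 2, 2] - a[:, 1, 2] * a[:, 2, 0])
        + a[:, 0, 2] * (a[:, 1, 0] * a[:, 2, 1] - a[:, 1, 1] * a[:, 2, 0])
    )
    return ms[np.abs(det) == 1].astype(np.float64)


def brute_force_min_lengths(metric: np.ndarray) -> np.ndarray:
    """Lexicographically minimal (a^2, b^2, c^2) over all enumerated
    integer basis transformations of the lattice metric ``metric``."""
    ms = unimodular_matrices()
    cols = [ms[:, :, i] for i in range(3)]
    diags = np.stack(
        [np.einsum("nj,jk,nk->n", c, metric, c) for c in cols], axis=1
    )
    order = np.lexsort((diags[:, 2], diags[:, 1], diags[:, 0]))
    return diags[order[0]]


# Hand-listed Laue 2/m operations (unique axis b), acting on column (h,k,l):
# identity, 2-fold along b, inversion, mirror normal to b.
LAUE_2M_OPS = [
    np.diag([1, 1, 1]),
    np.diag([-1, 1, -1]),
    np.diag([-1, -1, -1]),
    np.diag([1, -1, 1]),
]


def orbit_2m(hkl: tuple[int, int, int]) -> set[tuple[int, int, int]]:
    return {tuple(int(x) for x in op @ np.array(hkl)) for op in LAUE_2M_OPS}


def naive_best_subset(sets, k_max, d_min, cc_seed=0):
    """Full enumeration of dataset subsets, scored one by one.

    Independent of the package's search code: calls only the statistics
    routine on every explicitly enumerated combination and picks the maximum
    score with the (size, ids) tie-break.
    """
    import itertools

    from edmix.merge import merge_statistics
    from edmix.errors import EmptyStatisticsError, UnmergeablePairError

    by_id = sorted({s.dataset_id for s in sets})
    lookup = {s.dataset_id: s for s in sets}
    best = None
    for k in range(1, k_max + 1):
        for combo in itertools.combinations(by_id, k):
            try:
                score = merge_statistics([lookup[i] for i in combo], d_min, cc_seed=cc_seed)
            except (UnmergeablePairError, EmptyStatisticsError):
                continue
            key = (-score.score, len(combo), combo)
            if best is None or key < best[0]:
                best = (key, score)
    assert best is not None
    return best[1]
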