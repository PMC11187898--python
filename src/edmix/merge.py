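"""Merging statistics and best-subset selection for partial-wedge datasets.

Each crystal contributes a short-wedge reflection list (h, k, l, I, sigma).
Reflections are mapped to a canonical representative of their symmetry orbit
(the reciprocal-space asymmetric unit of the Laue group, including Friedel
inversion), datasets are brought to a common scale by one multiplicative
factor each, and standard quality statistics are computed over the merged
groups:

* completeness — observed unique reflections over the theoretically possible
  unique reflections within the resolution sphere (counted by direct
  enumeration of integer triples);
* R_merge = sum_hkl sum_i |I_i - <I>| / sum_hkl sum_i I_i and the
  multiplicity-weighted R_meas with the sqrt(n/(n-1)) prefactor, both over
  groups observed at least twice;
* CC1/2 — Pearson correlation between mean intensities of two random
  half-splits of each multiplicity >= 2 group.

``best_subset`` searches subsets of datasets (exhaustively up to a budget, or
greedily) for the subset maximising a weighted score
``completeness/100 + CC1/2 - R_meas``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .cells import UnitCell, cell_to_metric
from .errors import (
    BudgetExceededError,
    ConfigurationError,
    EmptyStatisticsError,
    InputError,
    UnmergeablePairError,
)

__all__ = [
    "ReflectionSet",
    "MergeScore",
    "LAUE_GROUPS",
    "laue_operators",
    "map_to_asu",
    "resolution",
    "count_theoretical_unique",
    "scale_datasets",
    "merge_statistics",
    "best_subset",
]

# ---------------------------------------------------------------------------
# Laue-group symmetry
# ---------------------------------------------------------------------------

_I3 = ((1, 0, 0), (0, 1, 0), (0, 0, 1))
_INV = ((-1, 0, 0), (0, -1, 0), (0, 0, -1))
_2C = ((-1, 0, 0), (0, -1, 0), (0, 0, 1))  # 2-fold along c
_2B = ((-1, 0, 0), (0, 1, 0), (0, 0, -1))  # 2-fold along b (unique axis b)
_2A = ((1, 0, 0), (0, -1, 0), (0, 0, -1))  # 2-fold along a
_4C = ((0, -1, 0), (1, 0, 0), (0, 0, 1))  # 4-fold along c
_3C = ((0, -1, 0), (1, -1, 0), (0, 0, 1))  # 3-fold along c, hexagonal axes
_2HEX = ((0, 1, 0), (1, 0, 0), (0, 0, -1))  # 2-fold along [110], hexagonal
_3D = ((0, 0, 1), (1, 0, 0), (0, 1, 0))  # 3-fold along [111], cubic

#: Generators per Laue group (Friedel inversion added automatically).
_GENERATORS: dict[str, tuple[tuple, ...]] = {
    "-1": (),
    "2/m": (_2B,),
    "mmm": (_2A, _2B),
    "4/m": (_4C,),
    "4/mmm": (_4C, _2A),
    "-3": (_3C,),
    "-3m": (_3C, _2HEX),
    "6/m": (_3C, _2C),
    "6/mmm": (_3C, _2C, _2HEX),
    "m-3": (_2A, _2B, _3D),
    "m-3m": (_2A, _2B, _3D, _4C),
}

LAUE_GROUPS = tuple(_GENERATORS)


@lru_cache(maxsize=None)
def laue_operators(laue_group: str) -> np.ndarray:
    """All rotation matrices of the Laue group (point group plus Friedel
    inversion), as an (n, 3, 3) integer array, closed under multiplication."""
    if laue_group not in _GENERATORS:
        raise ConfigurationError(
            f"unsupported Laue group {laue_group!r}; one of {sorted(_GENERATORS)}"
        )
    ops = {_I3, _INV}
    gens = set(_GENERATORS[laue_group]) | ops
    changed = True
    while changed:
        changed = False
        for a, b in itertools.product(tuple(ops | gens), repeat=2):
            prod = tuple(
                tuple(int(x) for x in row)
                for row in (np.array(a) @ np.array(b))
            )
            if prod not in ops:
                ops.add(prod)
                changed = True
    arr = np.array(sorted(ops), dtype=int)
    return arr


def map_to_asu(h: int, k: int, l: int, laue_group: str) -> tuple[int, int, int]:
    """Canonical representative of the symmetry orbit of (h, k, l).

    Applies every operator of the Laue group (Friedel inversion included) and
    returns the lexicographically greatest equivalent index.  Idempotent.
    """
    ops = laue_operators(laue_group)
    orbit = ops @ np.array([h, k, l])
    best = max(map(tuple, orbit))
    return (int(best[0]), int(best[1]), int(best[2]))


def _map_many(hkl: np.ndarray, laue_group: str) -> np.ndarray:
    """Vectorised ASU mapping of an (n, 3) integer index array."""
    ops = laue_operators(laue_group)
    if len(hkl) == 0:
        return np.empty((0, 3), dtype=int)
    orbits = np.einsum("oij,nj->noi", ops, hkl)
    # lexicographically greatest (h, k, l) per orbit, via a scalar sort key
    span = int(np.abs(orbits).max()) + 1
    base = 2 * span + 1
    key = (orbits[..., 0] * base + orbits[..., 1]) * base + orbits[..., 2]
    pick = key.argmax(axis=1)
    return orbits[np.arange(len(hkl)), pick]


# ---------------------------------------------------------------------------
# Reflection containers
# ---------------------------------------------------------------------------


@dataclass
class ReflectionSet:
    """Reflection list from one wedge: the unit of merging.

    ``hkl`` is an (n, 3) integer array, ``intensity`` and ``sigma`` are
    length-n float arrays on an arbitrary common scale (sigma > 0).
    ``variant`` distinguishes alternative processing variants of the same
    physical dataset; subset search picks at most one variant per dataset.
    """

    dataset_id: str
    cell: UnitCell
    laue_group: str
    hkl: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    variant: str = ""

    def __post_init__(self) -> None:
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))
        self.intensity = np.asarray(self.intensity, dtype=float).ravel()
        self.sigma = np.asarray(self.sigma, dtype=float).ravel()
        if self.laue_group not in _GENERATORS:
            raise ConfigurationError(f"unsupported Laue group {self.laue_group!r}")
        if not (len(self.hkl) == len(self.intensity) == len(self.sigma)):
            raise InputError("hkl, intensity and sigma must have equal lengths")
        if (self.sigma <= 0).any():
            raise InputError(f"{self.dataset_id}: all sigmas must be positive")
        if (self.hkl == 0).all(axis=1).any():
            raise InputError(f"{self.dataset_id}: (0,0,0) is not a valid reflection")

    def __len__(self) -> int:
        return len(self.intensity)

    def unique_asu(self, d_min: float | None = None) -> np.ndarray:
        """Unique ASU-mapped indices, optionally cut at ``d_min``."""
        hkl = self.hkl
        if d_min is not None:
            d = resolution(hkl, self.cell)
            hkl = hkl[d >= d_min]
        if len(hkl) == 0:
            return np.empty((0, 3), dtype=int)
        return np.unique(_map_many(hkl, self.laue_group), axis=0)


@dataclass
class MergeScore:
    """Quality statistics of one merged subset of datasets."""

    subset: tuple[str, ...]
    completeness: float
    multiplicity: float
    r_merge: float
    r_meas: float
    cc_half: float
    score: float
    n_unique: int = 0
    n_observations: int = 0
    variants: tuple[str, ...] = field(default=())


# ---------------------------------------------------------------------------
# Resolution and theoretical completeness
# ---------------------------------------------------------------------------


def resolution(hkl: np.ndarray, cell: UnitCell) -> np.ndarray:
    """d-spacing (angstrom) for each (h, k, l) row, from the reciprocal metric."""
    g_star = np.linalg.inv(cell_to_metric(cell).matrix)
    hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
    inv_d2 = np.einsum("ni,ij,nj->n", hkl, g_star, hkl)
    with np.errstate(divide="ignore"):
        return 1.0 / np.sqrt(inv_d2)


def count_theoretical_unique(cell: UnitCell, laue_group: str, d_min: float) -> int:
    """Number of symmetry-unique reflections with d >= d_min.

    Counts by direct enumeration of all integer triples inside the resolution
    sphere, mapped to the ASU — unambiguous at desk scale (d_min >= ~0.7 A,
    cells up to a few tens of angstroms).
    """
    if d_min <= 0:
        raise ConfigurationError("d_min must be positive")
    hmax = [int(length / d_min) + 1 for length in cell.lengths]
    if max(hmax) > 200:
        raise ConfigurationError("d_min too small for direct enumeration at this cell size")
    axes = [np.arange(-m, m + 1) for m in hmax]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[(grid != 0).any(axis=1)]
    d = resolution(grid, cell)
    grid = grid[d >= d_min]
    if len(grid) == 0:
        return 0
    return len(np.unique(_map_many(grid, laue_group), axis=0))


# ---------------------------------------------------------------------------
# Scaling and merged statistics
# ---------------------------------------------------------------------------

_MIN_COMMON = 3


def _asu_keys(rs: ReflectionSet) -> np.ndarray:
    return _map_many(rs.hkl, rs.laue_group)


def scale_datasets(
    sets: list[ReflectionSet], tol: float = 1e-6, max_iter: int = 100
) -> np.ndarray:
    """One least-squares multiplicative scale per dataset.

    Iteratively minimises sum over common unique reflections of
    ``(k_j * I_j - <I>)^2`` where ``<I>`` is the current scaled group mean;
    the first dataset's scale is fixed at 1.  Requires every dataset to share
    at least three common unique reflections with the first (reference)
    dataset, directly or it cannot be put on a common scale.
    """
    if len(sets) < 2:
        return np.ones(len(sets))
    keys = [_asu_keys(rs) for rs in sets]
    ref_keys = {tuple(k) for k in keys[0]}
    for rs, kk in zip(sets[1:], keys[1:]):
        common = ref_keys.intersection(map(tuple, kk))
        if len(common) < _MIN_COMMON:
            raise UnmergeablePairError(
                f"datasets {sets[0].dataset_id!r} and {rs.dataset_id!r} share "
                f"only {len(common)} unique reflections (need >= {_MIN_COMMON})"
            )

    # index observations by unique reflection
    group_index: dict[tuple[int, int, int], int] = {}
    obs_group: list[np.ndarray] = []
    for kk in keys:
        gi = np.empty(len(kk), dtype=int)
        for i, key in enumerate(map(tuple, kk)):
            gi[i] = group_index.setdefault(key, len(group_index))
        obs_group.append(gi)
    n_groups = len(group_index)

    scales = np.ones(len(sets))
    for _ in range(max_iter):
        # group means under current scales
        sums = np.zeros(n_groups)
        counts = np.zeros(n_groups)
        for rs, gi, k in zip(sets, obs_group, scales):
            np.add.at(sums, gi, k * rs.intensity)
            np.add.at(counts, gi, 1.0)
        means = sums / np.maximum(counts, 1)
        new_scales = scales.copy()
        for j, (rs, gi) in enumerate(zip(sets, obs_group)):
            ibar = means[gi]
            denom = float(rs.intensity @ rs.intensity)
            if denom > 0:
                # scale factors are physical (positive); an anti-correlated
                # dataset is pinned near zero rather than sign-flipped
                new_scales[j] = max(float(rs.intensity @ ibar) / denom, 1e-8)
        new_scales /= new_scales[0]
        # keep pathological (anti-correlated) fits from diverging
        new_scales = np.clip(new_scales, 1e-8, 1e8)
        if np.max(np.abs(new_scales - scales)) < tol:
            scales = new_scales
            break
        scales = new_scales
    return scales


def merge_statistics(
    sets: list[ReflectionSet],
    d_min: float,
    cc_seed: int = 0,
    scales: np.ndarray | None = None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> MergeScore:
    """Merged quality statistics for a set of (scaled) reflection lists.

    ``scales`` defaults to :func:`scale_datasets` for multiple datasets.
    ``weights`` are the (completeness, CC1/2, R_meas) coefficients of the
    composite score ``w0 * completeness/100 + w1 * CC1/2 - w2 * R_meas``.
    """
    if not sets:
        raise EmptyStatisticsError("no datasets given")
    if scales is None:
        scales = scale_datasets(sets) if len(sets) > 1 else np.ones(len(sets))

    cell = sets[0].cell
    laue = sets[0].laue_group
    groups: dict[tuple[int, int, int], list[float]] = {}
    for rs, k in zip(sets, scales):
        d = resolution(rs.hkl, rs.cell)
        keep = d >= d_min
        keys = _map_many(rs.hkl[keep], rs.laue_group)
        for key, inten in zip(map(tuple, keys), k * rs.intensity[keep]):
            groups.setdefault(key, []).append(float(inten))
    if not groups:
        raise EmptyStatisticsError(f"no unique reflections with d >= {d_min}")

    n_unique = len(groups)
    n_obs = sum(len(v) for v in groups.values())
    n_theory = count_theoretical_unique(cell, laue, d_min)
    completeness = 100.0 * n_unique / n_theory if n_theory else 0.0
    multiplicity = n_obs / n_unique

    # R factors over multiplicity >= 2 groups
    num_merge = num_meas = denom = 0.0
    multi = {k: v for k, v in groups.items() if len(v) >= 2}
    for vals in multi.values():
        arr = np.asarray(vals)
        mean = arr.mean()
        dev = np.abs(arr - mean).sum()
        n = len(arr)
        num_merge += dev
        num_meas += math.sqrt(n / (n - 1)) * dev
        # |I| keeps the denominator meaningful for pathological negative data
        denom += np.abs(arr).sum()
    r_merge = num_merge / denom if denom > 0 else 0.0
    r_meas = num_meas / denom if denom > 0 else 0.0

    cc_half = _cc_half(multi, cc_seed)

    score = (
        weights[0] * completeness / 100.0 + weights[1] * cc_half - weights[2] * r_meas
    )
    return MergeScore(
        subset=tuple(rs.dataset_id for rs in sets),
        completeness=completeness,
        multiplicity=multiplicity,
        r_merge=r_merge,
        r_meas=r_meas,
        cc_half=cc_half,
        score=score,
        n_unique=n_unique,
        n_observations=n_obs,
        variants=tuple(rs.variant for rs in sets),
    )


def _cc_half(multi: dict[tuple[int, int, int], list[float]], cc_seed: int) -> float:
    """Pearson correlation between mean intensities of two random half-splits.

    Groups are split by a seeded permutation.  Degenerate cases: with fewer
    than two multiplicity >= 2 groups, or when either half-vector is
    constant, CC1/2 is 1 if the halves agree element-wise and 0 otherwise.
    """
    rng = np.random.default_rng(cc_seed)
    half1, half2 = [], []
    for key in sorted(multi):
        vals = np.asarray(multi[key])
        perm = rng.permutation(len(vals))
        cut = len(vals) // 2
        half1.append(vals[perm[:cut]].mean())
        half2.append(vals[perm[cut:]].mean())
    h1 = np.asarray(half1)
    h2 = np.asarray(half2)
    if len(h1) == 0:
        return 0.0
    if np.array_equal(h1, h2):
        return 1.0  # exact for noise-free statistically identical halves
    if len(h1) < 2 or h1.std() == 0 or h2.std() == 0:
        return 0.0
    return float(np.corrcoef(h1, h2)[0, 1])


# ---------------------------------------------------------------------------
# Subset search
# ---------------------------------------------------------------------------


def _group_variants(sets: list[ReflectionSet]) -> dict[str, list[ReflectionSet]]:
    grouped: dict[str, list[ReflectionSet]] = {}
    for rs in sets:
        grouped.setdefault(rs.dataset_id, []).append(rs)
    return grouped


def _score_subset(
    subset: list[ReflectionSet], d_min: float, cc_seed: int, weights
) -> MergeScore | None:
    try:
        return merge_statistics(subset, d_min, cc_seed=cc_seed, weights=weights)
    except (UnmergeablePairError, EmptyStatisticsError):
        return None


def best_subset(
    sets: list[ReflectionSet],
    k_max: int,
    d_min: float,
    strategy: str = "exhaustive",
    cc_seed: int = 0,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    budget: int = 10**6,
) -> MergeScore:
    """Best-scoring subset of at most ``k_max`` datasets.

    ``exhaustive`` evaluates every combination of datasets of size 1..k_max
    (choosing at most one processing variant per dataset) and returns the
    maximal score; ties break by smaller subset size, then lexicographic ids.
    ``greedy`` grows the best singleton by best marginal addition until
    ``k_max`` or no improvement.  Exhaustive enumeration beyond ``budget``
    combinations raises :class:`BudgetExceededError` instructing the greedy
    fallback.  Subsets that cannot be scaled pairwise are skipped.
    """
    grouped = _group_variants(sets)
    ids = sorted(grouped)
    if not 1 <= k_max <= len(ids):
        raise ConfigurationError(f"k_max must be in [1, {len(ids)}], got {k_max}")
    if strategy not in ("exhaustive", "greedy"):
        raise ConfigurationError(f"unknown strategy {strategy!r}")

    def better(a: MergeScore, b: MergeScore | None) -> bool:
        if b is None:
            return True
        return (-a.score, len(a.subset), a.subset) < (-b.score, len(b.subset), b.subset)

    if strategy == "exhaustive":
        # number of combinations incl. variant choices: sum over k of the
        # elementary symmetric polynomials of the per-dataset variant counts
        esp = [1] + [0] * k_max
        for did in ids:
            v = len(grouped[did])
            for k in range(min(k_max, len(ids)), 0, -1):
                esp[k] += esp[k - 1] * v
        total = sum(esp[1 : k_max + 1])
        if total > budget:
            raise BudgetExceededError(
                f"{total} combinations exceed the budget of {budget}; "
                "fall back to strategy='greedy'"
            )
        best: MergeScore | None = None
        for k in range(1, k_max + 1):
            for combo in itertools.combinations(ids, k):
                for choice in itertools.product(*(grouped[i] for i in combo)):
                    res = _score_subset(list(choice), d_min, cc_seed, weights)
                    if res is not None and better(res, best):
                        best = res
        if best is None:
            raise EmptyStatisticsError("no scoreable subset found")
        return best

    # greedy
    best = None
    current: list[ReflectionSet] = []
    remaining = dict(grouped)
    while len(current) < k_max:
        step_best: MergeScore | None = None
        step_choice: ReflectionSet | None = None
        for did in sorted(remaining):
            for variant in remaining[did]:
                res = _score_subset(current + [variant], d_min, cc_seed, weights)
                if res is not None and better(res, step_best):
                    step_best = res
                    step_choice = variant
        if step_choice is None or (best is not None and step_best.score <= best.score):
            break
        current.append(step_choice)
        remaining.pop(step_choice.dataset_id)
        best = step_best
    if best is None:
        raise EmptyStatisticsError("no scoreable subset found")
    return best
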