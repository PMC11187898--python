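"""Symmetry mapping, scaling, merging statistics and subset search."""

import numpy as np
import pytest

from edmix.cells import UnitCell
from edmix.errors import (
    BudgetExceededError,
    ConfigurationError,
    EmptyStatisticsError,
    InputError,
    UnmergeablePairError,
)
from edmix.merge import (
    LAUE_GROUPS,
    ReflectionSet,
    best_subset,
    count_theoretical_unique,
    laue_operators,
    map_to_asu,
    merge_statistics,
    resolution,
    scale_datasets,
)
from edmix.synthetic import default_library, generate_reflections

from .oracles import naive_best_subset, orbit_2m

CUBIC = UnitCell(10, 10, 10, 90, 90, 90)

_EXPECTED_ORDER = {
    "-1": 2, "2/m": 4, "mmm": 8, "4/m": 8, "4/mmm": 16,
    "-3": 6, "-3m": 12, "6/m": 12, "6/mmm": 24, "m-3": 24, "m-3m": 48,
}


class TestSymmetry:
    @pytest.mark.parametrize("laue", LAUE_GROUPS)
    def test_group_orders(self, laue):
        ops = laue_operators(laue)
        assert len(ops) == _EXPECTED_ORDER[laue]
        # closed under multiplication
        as_set = {tuple(map(tuple, m)) for m in ops}
        for a in ops[:6]:
            for b in ops[:6]:
                assert tuple(map(tuple, a @ b)) in as_set

    def test_friedel_pair_maps_together(self):
        assert map_to_asu(-1, -2, -3, "-1") == (1, 2, 3)
        assert map_to_asu(1, 2, 3, "-1") == (1, 2, 3)

    def test_2m_orbit_against_hand_listed_operations(self):
        # brute-force orbit from the four hand-listed 2/m operations
        for hkl in [(1, 2, 3), (-1, 2, -3), (0, 1, 2), (3, 0, -1)]:
            orbit = orbit_2m(hkl)
            canon = {map_to_asu(*h, "2/m") for h in orbit}
            assert len(canon) == 1
            assert canon.pop() == max(orbit)

    @pytest.mark.parametrize("laue", LAUE_GROUPS)
    def test_idempotence_and_orbit_invariance(self, laue, rng):
        for _ in range(10):
            hkl = tuple(int(x) for x in rng.integers(-5, 6, 3))
            if hkl == (0, 0, 0):
                continue
            canon = map_to_asu(*hkl, laue)
            assert map_to_asu(*canon, laue) == canon
            # every orbit member maps to the same representative
            for op in laue_operators(laue):
                equiv = tuple(int(x) for x in op @ np.array(hkl))
                assert map_to_asu(*equiv, laue) == canon

    def test_unsupported_group_rejected(self):
        with pytest.raises(ConfigurationError):
            map_to_asu(1, 2, 3, "P212121")


class TestReflectionSet:
    def test_sigma_must_be_positive(self):
        with pytest.raises(InputError):
            ReflectionSet("d", CUBIC, "-1", [[1, 0, 0]], [5.0], [0.0])

    def test_origin_reflection_rejected(self):
        with pytest.raises(InputError):
            ReflectionSet("d", CUBIC, "-1", [[0, 0, 0]], [5.0], [1.0])


class TestScaling:
    def _pair(self, factor):
        hkl = [[1, 0, 0], [0, 2, 0], [1, 1, 1], [2, 1, 0]]
        inten = np.array([10.0, 20.0, 30.0, 40.0])
        d1 = ReflectionSet("d1", CUBIC, "-1", hkl, inten, np.ones(4))
        d2 = ReflectionSet("d2", CUBIC, "-1", hkl, factor * inten, np.ones(4))
        return [d1, d2]

    def test_identical_datasets_scale_to_unity(self):
        assert np.allclose(scale_datasets(self._pair(1.0)), [1.0, 1.0])

    def test_doubled_dataset_gets_half_scale(self):
        scales = scale_datasets(self._pair(2.0))
        assert scales[0] == pytest.approx(1.0)
        assert scales[1] == pytest.approx(0.5, rel=1e-6)

    def test_insufficient_overlap_raises(self):
        d1 = ReflectionSet("d1", CUBIC, "-1", [[1, 0, 0], [0, 1, 0]], [1.0, 2.0], [0.1, 0.1])
        d2 = ReflectionSet("d2", CUBIC, "-1", [[5, 0, 0], [0, 5, 0]], [1.0, 2.0], [0.1, 0.1])
        with pytest.raises(UnmergeablePairError):
            scale_datasets([d1, d2])

    def test_recovers_generating_scales_within_2_percent(self, library):
        comp = library[0]
        true_scales = [1.0, 1.7, 0.6]
        sets = [
            generate_reflections(
                comp, d_min=1.2, wedge_fraction=0.7, scale=s, noise_frac=0.02,
                seed=10 + i, dataset_id=f"w{i}", intensity_seed=99,
            )
            for i, s in enumerate(true_scales)
        ]
        scales = scale_datasets(sets)
        # recovered k_j should invert the generating scale (relative to d0)
        for k, s in zip(scales, true_scales):
            assert k * s == pytest.approx(1.0, rel=0.02)


class TestMergeStatistics:
    def test_two_observation_group_hand_formulas(self):
        rs = ReflectionSet(
            "toy", CUBIC, "-1", [[1, 2, 3], [1, 2, 3]], [10.0, 12.0], [1.0, 1.0]
        )
        score = merge_statistics([rs], d_min=2.0)
        assert score.r_merge == pytest.approx(2.0 / 22.0)
        assert score.r_meas == pytest.approx(np.sqrt(2.0) * 2.0 / 22.0)

    def test_perfect_data_has_zero_r_and_unit_cc(self):
        rs = ReflectionSet(
            "perfect", CUBIC, "-1",
            [[1, 0, 0]] * 2 + [[0, 1, 1]] * 2, [5.0, 5.0, 9.0, 9.0], [0.1] * 4,
        )
        score = merge_statistics([rs], d_min=3.0)
        assert score.r_merge == 0.0
        assert score.cc_half == 1.0

    def test_full_coverage_gives_100_percent_completeness(self, library):
        comp = library[1]
        rs = generate_reflections(comp, d_min=1.2, wedge_fraction=1.0, noise_frac=0.0, seed=1)
        score = merge_statistics([rs], d_min=1.2)
        assert score.completeness == pytest.approx(100.0)
        assert score.r_merge == 0.0

    def test_r_factors_scale_invariant(self, library):
        comp = library[2]
        sets = [
            generate_reflections(comp, d_min=1.3, wedge_fraction=0.5, noise_frac=0.05,
                                 seed=s, dataset_id=f"w{s}", intensity_seed=7)
            for s in range(3)
        ]
        base = merge_statistics(sets, d_min=1.3, cc_seed=5)
        scaled_sets = [
            ReflectionSet(rs.dataset_id, rs.cell, rs.laue_group, rs.hkl,
                          rs.intensity * 37.0, rs.sigma * 37.0)
            for rs in sets
        ]
        scaled = merge_statistics(scaled_sets, d_min=1.3, cc_seed=5)
        assert scaled.r_merge == pytest.approx(base.r_merge, rel=1e-9)
        assert scaled.r_meas == pytest.approx(base.r_meas, rel=1e-9)
        assert scaled.completeness == pytest.approx(base.completeness)

    def test_r_meas_strictly_exceeds_r_merge_for_finite_multiplicity(self, library):
        comp = library[0]
        sets = [
            generate_reflections(comp, d_min=1.3, wedge_fraction=0.6, noise_frac=0.08,
                                 seed=s, dataset_id=f"w{s}", intensity_seed=3)
            for s in range(2)
        ]
        score = merge_statistics(sets, d_min=1.3)
        assert score.r_meas > score.r_merge > 0

    def test_no_reflections_within_limit_raises(self):
        rs = ReflectionSet("d", CUBIC, "-1", [[1, 0, 0]], [5.0], [1.0])
        with pytest.raises(EmptyStatisticsError):
            merge_statistics([rs], d_min=11.0)

    def test_theoretical_count_triclinic_by_hand(self):
        # 10 A cubic cell, d_min 5 A, Laue -1: |h|<=2 sphere of radius 1/5
        # enumerate by hand: (1,0,0)x3, (1,1,0)x6/2.. easier: direct small check
        n = count_theoretical_unique(CUBIC, "-1", 5.0)
        # integer triples with h^2+k^2+l^2 <= 4 (i.e. |H| <= 0.2), half sphere
        full = [
            (h, k, l)
            for h in range(-2, 3)
            for k in range(-2, 3)
            for l in range(-2, 3)
            if (h, k, l) != (0, 0, 0) and h * h + k * k + l * l <= 4
        ]
        assert n == len(full) // 2


@pytest.fixture(scope="module")
def five_sets(library):
    comp = library[0]
    return [
        generate_reflections(
            comp, d_min=1.3, wedge_fraction=0.35, scale=s, noise_frac=0.05,
            seed=20 + i, dataset_id=f"w{i}", intensity_seed=77,
        )
        for i, s in enumerate([1.0, 0.9, 1.2, 0.7, 1.1])
    ]


class TestBestSubset:

    def test_exhaustive_matches_naive_enumeration(self, five_sets):
        ours = best_subset(five_sets, k_max=3, d_min=1.3, cc_seed=4)
        oracle = naive_best_subset(five_sets, k_max=3, d_min=1.3, cc_seed=4)
        assert ours.subset == oracle.subset
        assert ours.score == pytest.approx(oracle.score)

    def test_completeness_monotone_under_inclusion(self, five_sets):
        singles = merge_statistics(five_sets[:1], d_min=1.3)
        pair = merge_statistics(five_sets[:2], d_min=1.3)
        trio = merge_statistics(five_sets[:3], d_min=1.3)
        assert singles.completeness <= pair.completeness <= trio.completeness

    def test_exact_copies_never_decrease_completeness(self, five_sets):
        rs = five_sets[0]
        copy = ReflectionSet("w0_copy", rs.cell, rs.laue_group, rs.hkl, rs.intensity, rs.sigma)
        one = merge_statistics([rs], d_min=1.3)
        two = merge_statistics([rs, copy], d_min=1.3)
        assert two.completeness >= one.completeness

    def test_poisoned_dataset_excluded_from_winner(self, five_sets):
        rs = five_sets[1]
        poisoned = ReflectionSet(
            "poison", rs.cell, rs.laue_group, rs.hkl, -rs.intensity, rs.sigma
        )
        sets = five_sets[:3] + [poisoned]
        winner = best_subset(sets, k_max=3, d_min=1.3, cc_seed=4)
        assert "poison" not in winner.subset
        oracle = naive_best_subset(sets, k_max=3, d_min=1.3, cc_seed=4)
        assert "poison" not in oracle.subset

    def test_greedy_never_beats_exhaustive(self, five_sets):
        ex = best_subset(five_sets, k_max=3, d_min=1.3, cc_seed=4)
        gr = best_subset(five_sets, k_max=3, d_min=1.3, strategy="greedy", cc_seed=4)
        assert gr.score <= ex.score + 1e-12

    def test_budget_exceeded_instructs_greedy(self, five_sets):
        with pytest.raises(BudgetExceededError, match="greedy"):
            best_subset(five_sets, k_max=3, d_min=1.3, budget=2)

    def test_variant_axis_picks_at_most_one_per_dataset(self, five_sets):
        rs = five_sets[0]
        variant = ReflectionSet(
            rs.dataset_id, rs.cell, rs.laue_group, rs.hkl,
            rs.intensity * 1.01, rs.sigma, variant="alt",
        )
        winner = best_subset(five_sets + [variant], k_max=3, d_min=1.3, cc_seed=4)
        assert len(winner.subset) == len(set(winner.subset))


class TestResolution:
    def test_cubic_axial_reflection(self):
        d = resolution([[2, 0, 0]], CUBIC)
        assert d[0] == pytest.approx(5.0)

    def test_orthorhombic_formula(self):
        cell = UnitCell(5, 8, 13, 90, 90, 90)
        d = resolution([[1, 2, 3]], cell)
        expected = (1 / 25 + 4 / 64 + 9 / 169) ** -0.5
        assert d[0] == pytest.approx(expected)
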