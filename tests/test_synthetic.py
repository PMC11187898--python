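"""Synthetic campaign generator: reproducibility, statistics, coverage."""

import numpy as np
import pandas as pd
import pytest

from edmix.classify import Status, classify_campaign
from edmix.composition import build_report, compare_to_input
from edmix.errors import GenerationError, SpecError
from edmix.merge import merge_statistics
from edmix.synthetic import (
    MixtureSpec,
    default_fractions,
    default_library,
    generate_campaign,
    generate_reflections,
    render_crystal_image,
)


class TestMixtureSpec:
    def test_fractions_must_sum_to_100(self, library):
        with pytest.raises(SpecError):
            MixtureSpec(compounds=[(library[0], 50.0), (library[1], 40.0)])

    def test_probabilities_must_sum_below_one(self):
        with pytest.raises(SpecError):
            MixtureSpec.default(n_crystals=10, p_no_diffraction=0.9, p_weak=0.2)

    def test_default_spec_covers_nine_compounds(self):
        spec = MixtureSpec.default()
        assert len(spec.compounds) == 9
        assert sum(f for _, f in spec.compounds) == pytest.approx(100.0)


class TestCampaign:
    def test_same_seed_gives_identical_output(self):
        a_obs, a_truth = generate_campaign(MixtureSpec.default(n_crystals=50, seed=9))
        b_obs, b_truth = generate_campaign(MixtureSpec.default(n_crystals=50, seed=9))
        pd.testing.assert_frame_equal(a_truth, b_truth)
        assert [o.observed_cell.parameters if o.observed_cell else None for o in a_obs] == [
            o.observed_cell.parameters if o.observed_cell else None for o in b_obs
        ]

    def test_noiseless_failure_free_campaign_is_exact(self, library):
        spec = MixtureSpec.default(n_crystals=100, seed=2)
        spec.cell_noise = (0.0, 0.0)
        spec.p_no_diffraction = spec.p_weak = spec.p_multi = spec.p_smeared = 0.0
        obs, truth = generate_campaign(spec)
        by_name = {c.name: c for c in library}
        for o, (_, row) in zip(obs, truth.iterrows()):
            assert o.status is Status.INDEXED
            assert o.observed_cell.isclose(by_name[row["true_compound"]].cell)

    def test_indexed_fraction_within_binomial_interval(self):
        spec = MixtureSpec.default(
            n_crystals=10000, seed=6, p_no_diffraction=0.2, p_weak=0.05,
            p_multi=0.0, p_smeared=0.0,
        )
        obs, _ = generate_campaign(spec)
        n_indexed = sum(1 for o in obs if o.status is Status.INDEXED)
        p = 0.75
        sd = np.sqrt(p * (1 - p) * len(obs))
        assert abs(n_indexed - p * len(obs)) <= 3 * sd

    def test_single_compound_recovers_100_percent(self, library):
        spec = MixtureSpec(compounds=[(library[0], 100.0)], n_crystals=100, seed=1)
        obs, _ = generate_campaign(spec)
        matches, _ = classify_campaign(obs, library)
        rep = build_report(matches, obs)
        assert list(rep.table["compound"]) == [library[0].name]
        assert rep.table["counting_ratio"].iloc[0] == pytest.approx(100.0)

    def test_cell_noise_sd_matches_requested_sigma(self, library):
        spec = MixtureSpec(compounds=[(library[0], 100.0)], n_crystals=1000, seed=8)
        spec.p_no_diffraction = spec.p_weak = spec.p_multi = spec.p_smeared = 0.0
        obs, _ = generate_campaign(spec)
        ref = library[0].cell
        dev_a = np.array([o.observed_cell.a - ref.a for o in obs])
        assert np.std(dev_a, ddof=1) == pytest.approx(spec.cell_noise[0], rel=0.10)
        dev_al = np.array([o.observed_cell.alpha - ref.alpha for o in obs])
        assert np.std(dev_al, ddof=1) == pytest.approx(spec.cell_noise[1], rel=0.10)

    def test_failure_multiplier_suppresses_one_compound(self, library):
        spec = MixtureSpec.default(n_crystals=2000, seed=13)
        spec.failure_multipliers = {"L-Cysteine": 3.0}
        obs, truth = generate_campaign(spec)
        df = truth.copy()
        df["indexed"] = [o.status is Status.INDEXED for o in obs]
        rate = df.groupby(df["true_compound"] == "L-Cysteine")["indexed"].mean()
        assert rate[True] < rate[False]

    def test_end_to_end_recovery_within_two_points(self, library):
        spec = MixtureSpec.default(n_crystals=1000, seed=17)
        obs, _ = generate_campaign(spec)
        matches, _ = classify_campaign(obs, library)
        rep = build_report(matches, obs, compounds=[c.name for c in library])
        errors, _ = compare_to_input(rep, default_fractions())
        assert np.mean(np.abs(list(errors.values()))) <= 2.0


class TestImages:
    def test_zero_area_request_rejected(self):
        with pytest.raises(GenerationError):
            render_crystal_image(0.0)

    def test_oversized_crystal_rejected(self):
        with pytest.raises(GenerationError):
            render_crystal_image(50.0, pixel_size=0.01, image_size=64)

    def test_true_pixel_count_matches_requested_area(self):
        img, true_px = render_crystal_image(0.5, pixel_size=0.01, seed=0)
        assert true_px == pytest.approx(0.5 / 0.01**2, rel=0.02)

    def test_same_seed_same_image(self):
        a, na = render_crystal_image(0.3, seed=5)
        b, nb = render_crystal_image(0.3, seed=5)
        assert na == nb
        assert np.array_equal(a, b)


class TestReflections:
    def test_full_wedge_noise_free_is_perfect(self, library):
        rs = generate_reflections(library[0], d_min=1.3, wedge_fraction=1.0, noise_frac=0.0)
        score = merge_statistics([rs], d_min=1.3)
        assert score.completeness == pytest.approx(100.0)
        assert score.r_merge == 0.0

    def test_union_of_wedges_beats_any_single(self, library):
        sets = [
            generate_reflections(library[0], d_min=1.3, wedge_fraction=0.3,
                                 seed=s, dataset_id=f"w{s}", intensity_seed=55)
            for s in range(5)
        ]
        merged = merge_statistics(sets, d_min=1.3)
        best_single = max(
            merge_statistics([rs], d_min=1.3).completeness for rs in sets
        )
        assert merged.completeness > best_single

    def test_wedge_fraction_validated(self, library):
        with pytest.raises(GenerationError):
            generate_reflections(library[0], wedge_fraction=0.0)


def test_default_library_loads_nine_compounds():
    lib = default_library()
    assert len(lib) == 9
    assert len({c.name for c in lib}) == 9
    # cells are pairwise well separated once reduced (no matching ambiguity)
    from edmix.cells import niggli_reduce

    reduced = [sorted(niggli_reduce(c.cell)[0].lengths) for c in lib]
    for i in range(9):
        for j in range(i + 1, 9):
            gap = max(abs(x - y) for x, y in zip(reduced[i], reduced[j]))
            assert gap > 0.5
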