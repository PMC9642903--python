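import numpy as np
import pytest

from chromafill.colorspace import rgb_to_opponent
from chromafill.stimuli import (
    GridIllusionSpec,
    ProfileCut,
    SquareStimulusSpec,
    apply_illumination,
    compare_profiles,
    extract_profile,
    grayscale_base,
    grid_mask,
    make_assimilation_grid,
    make_color_scene,
    make_square,
    square_mask,
)


class TestSquares:
    def test_exact_pixel_count(self):
        spec = SquareStimulusSpec(canvas=(90, 90), side=5)
        img = make_square(spec)
        n_fill = np.sum(np.all(img == np.array(spec.fill_rgb), axis=-1))
        assert n_fill == 25
        assert square_mask(spec).sum() == 25

    def test_fill_equal_background_gives_constant_image(self):
        spec = SquareStimulusSpec(side=10, fill_rgb=(0.5,) * 3, background_rgb=(0.5,) * 3)
        assert np.ptp(make_square(spec)) == 0.0

    def test_red_square_rg_plane_positive_inside_zero_outside(self):
        spec = SquareStimulusSpec(canvas=(40, 40), side=10)
        opp = rgb_to_opponent(make_square(spec))
        mask = square_mask(spec)
        assert np.all(opp.rg[mask] == pytest.approx(0.5))
        assert np.all(opp.rg[~mask] == pytest.approx(0.0))

    def test_oversized_square_rejected(self):
        with pytest.raises(ValueError):
            SquareStimulusSpec(canvas=(20, 20), side=30)


class TestAssimilationGrid:
    def test_zero_saturation_reduces_to_grayscale_base(self, rng):
        scene = make_color_scene(shape=(60, 80), seed=1)
        spec = GridIllusionSpec(color_source=scene, saturation_ratio=0.0)
        out = make_assimilation_grid(spec)
        assert np.allclose(out, grayscale_base(scene), atol=1e-10)

    def test_grid_coverage_matches_geometry(self):
        scene = np.full((512, 512, 3), 0.5)
        spec = GridIllusionSpec(color_source=scene, line_width=3, step=15)
        frac = grid_mask(spec).mean()
        assert frac == pytest.approx(3.0 / 15.0, rel=0.02)

    def test_denser_grid_has_more_colored_pixels(self):
        scene = make_color_scene(shape=(90, 120), seed=0)
        n15 = grid_mask(GridIllusionSpec(color_source=scene, step=15)).sum()
        n50 = grid_mask(GridIllusionSpec(color_source=scene, step=50)).sum()
        assert n15 > n50

    def test_off_grid_pixels_exactly_grayscale(self):
        scene = make_color_scene(shape=(50, 70), seed=2)
        spec = GridIllusionSpec(color_source=scene, step=20)
        out = make_assimilation_grid(spec)
        off = ~grid_mask(spec)
        assert np.array_equal(out[off], grayscale_base(scene)[off])

    def test_step_not_exceeding_width_rejected(self):
        with pytest.raises(ValueError):
            GridIllusionSpec(color_source=np.zeros((10, 10, 3)), line_width=5, step=5)

    def test_mask_regeneration_idempotent(self):
        scene = np.zeros((64, 64, 3))
        spec = GridIllusionSpec(color_source=scene)
        assert np.array_equal(grid_mask(spec), grid_mask(spec))


class TestIllumination:
    def test_zero_strength_is_identity(self, rng):
        img = rng.random((10, 10, 3))
        assert np.array_equal(apply_illumination(img, (1.0, 0.8, 0.2), 0.0), img)

    def test_white_tint_is_identity_at_any_strength(self, rng):
        img = rng.random((10, 10, 3))
        assert np.allclose(apply_illumination(img, (1.0, 1.0, 1.0), 0.7), img)

    def test_yellow_tint_shifts_mean_by_toward_yellow(self, rng):
        img = rng.random((20, 20, 3))
        tinted = apply_illumination(img, (1.0, 0.9, 0.3), 0.9)
        # BY channel is positive toward yellow (blue weighted negatively)
        assert rgb_to_opponent(tinted).by.mean() > rgb_to_opponent(img).by.mean()


class TestProfiles:
    def test_constant_plane_gives_constant_profile(self):
        prof = extract_profile(np.full((20, 30), 0.4), ProfileCut(axis="row", position=10))
        assert np.allclose(prof, 0.4, atol=1e-12)
        assert prof.size == 30

    def test_centered_square_profile_symmetric_about_midline(self):
        spec = SquareStimulusSpec(canvas=(41, 41), side=11)
        plane = rgb_to_opponent(make_square(spec)).rg
        prof = extract_profile(plane, ProfileCut(axis="row", position=20))
        assert np.allclose(prof, prof[::-1], atol=1e-12)

    def test_zero_smoothing_equals_raw_band_average(self, rng):
        plane = rng.random((15, 25))
        cut = ProfileCut(axis="row", position=7, half_width=2, smoothing_sigma=0.0)
        assert np.allclose(extract_profile(plane, cut), plane[5:10].mean(axis=0))

    def test_cut_outside_image_rejected(self):
        with pytest.raises(ValueError):
            extract_profile(np.zeros((10, 10)), ProfileCut(axis="row", position=9, half_width=2))

    def test_column_cut_runs_along_rows(self):
        plane = np.tile(np.arange(12.0)[:, None], (1, 8))
        prof = extract_profile(plane, ProfileCut(axis="column", position=4, half_width=1,
                                                 smoothing_sigma=0.0))
        assert prof.size == 12
        assert np.allclose(prof, np.arange(12.0))


class TestProfileComparison:
    def test_profile_vs_itself_gives_perfect_fit(self, rng):
        prof = rng.random(60)
        cmp = compare_profiles(prof, prof)
        assert cmp.r_squared == pytest.approx(1.0)

    def test_affine_transform_preserves_r_squared(self, rng):
        prof = rng.random(60)
        cmp = compare_profiles(prof, 2.5 * prof - 0.3)
        assert cmp.r_squared == pytest.approx(1.0)
        assert cmp.slope == pytest.approx(2.5)

    def test_white_noise_reference_fits_poorly(self):
        # Monte-Carlo: independent noise should rarely exceed R^2 = 0.1
        rng = np.random.default_rng(0)
        base = rng.random(100)
        high = sum(
            compare_profiles(base, rng.standard_normal(100)).r_squared > 0.1
            for _ in range(100)
        )
        assert high <= 10

    def test_zero_variance_profile_flagged_undefined(self):
        cmp = compare_profiles(np.ones(30), np.arange(30.0))
        assert not cmp.defined
        assert np.isnan(cmp.r_squared)

    def test_edge_anchored_alignment_crops_overhang(self):
        sim = np.concatenate([np.zeros(10), np.ones(20)])
        ref = np.concatenate([np.zeros(5), np.ones(20), np.zeros(5)])
        cmp = compare_profiles(sim, ref, sim_edge=10, ref_edge=5)
        assert cmp.n == 25
        assert cmp.r_squared == pytest.approx(1.0)
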