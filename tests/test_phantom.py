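"""Phantom generator: geometry, Beer-Lambert optics, speckle statistics,
temporal decorrelation, and cohort bookkeeping."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from meoct import (
    PRESET_NAMES,
    PhantomScene,
    TissueRegion,
    build_cohort,
    build_ear,
    make_scene,
    rasterize,
    render_mean_intensity,
    sample_repeat_stack,
    sample_speckle_volume,
)
from meoct.phantom import REGION_LABELS, _default_optics


def beer_lambert_oracle(scene, back, atten):
    """Slow per-A-line cumulative-product rendering, independent of the
    vectorized implementation."""
    dz = scene.pixel_spacing[2]
    ny, nx, nz = scene.grid_shape
    back = np.asarray(back, dtype=np.float64)
    atten = np.asarray(atten, dtype=np.float64)
    mu = np.empty((ny, nx, nz))
    for y in range(ny):
        for x in range(nx):
            trans = 1.0
            for z in range(nz):
                mu[y, x, z] = back[y, x, z] * trans + scene.noise_floor
                trans *= np.exp(-2.0 * atten[y, x, z] * dz)
    return mu


class TestSceneValidation:
    def test_normal_preset_has_no_mass(self, tiny_grid):
        scene = make_scene("normal", 0, grid_shape=tiny_grid)
        assert scene.mass is None
        with pytest.raises(ValueError):
            glomus = make_scene("glomus", 0, grid_shape=tiny_grid)
            PhantomScene(class_preset="normal", seed=0, mass=glomus.mass)

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            PhantomScene(class_preset="normal", seed=0, grid_shape=(0, 4, 4))

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            make_scene("otosclerosis", 0)

    def test_landmarks_inside_grid(self, tiny_grid):
        for preset in PRESET_NAMES:
            truth, _, _ = rasterize(make_scene(preset, 3, grid_shape=tiny_grid))
            for coords in truth.landmarks.values():
                assert all(0 <= c < n for c, n in zip(coords, tiny_grid))

    def test_optics_invariants(self):
        with pytest.raises(ValueError):
            TissueRegion("tm", -1.0, 0.5)
        with pytest.raises(ValueError):
            TissueRegion("tm", 1.0, 0.5, flow_rho=1.5)


class TestTruthInvariants:
    @pytest.mark.parametrize("preset", PRESET_NAMES)
    def test_label_rho_and_mask_consistency(self, preset, tiny_grid):
        truth, _, _ = rasterize(make_scene(preset, 11, grid_shape=tiny_grid))
        assert truth.rho_map.min() >= 0.0 and truth.rho_map.max() <= 1.0
        # mass mask only where the rendered label says mass
        assert not np.any(truth.mass_mask & (truth.label_map != REGION_LABELS["mass"]))
        # air is static by definition
        assert np.all(truth.rho_map[truth.label_map == REGION_LABELS["air"]] == 1.0)

    def test_glomus_truth_is_vascular(self, tiny_grid):
        scene = make_scene("glomus", 5, grid_shape=tiny_grid)
        truth, _, _ = rasterize(scene)
        assert truth.mass_mask.sum() > 0
        assert truth.rho_map[truth.mass_mask].mean() < scene.rho_static


class TestMeanIntensity:
    def test_attenuation_free_limit(self, tiny_grid):
        scene = make_scene("normal", 2, grid_shape=tiny_grid)
        scene.optics = {
            name: dataclasses.replace(r, attenuation=0.0)
            for name, r in _default_optics().items()
        }
        truth, back, atten = rasterize(scene)
        mu = render_mean_intensity(scene)
        np.testing.assert_allclose(
            mu, back.astype(np.float64) + scene.noise_floor, rtol=1e-12
        )

    @pytest.mark.parametrize("preset", ["normal", "glomus"])
    def test_matches_per_aline_cumulative_product_oracle(self, preset):
        scene = make_scene(preset, 7, grid_shape=(4, 12, 40))
        _, back, atten = rasterize(scene)
        mu = render_mean_intensity(scene)
        np.testing.assert_allclose(mu, beer_lambert_oracle(scene, back, atten),
                                   rtol=1e-9)

    @pytest.mark.parametrize("preset", ["glomus", "cholesteatoma"])
    def test_mass_shadows_promontory(self, preset, small_grid):
        # identical geometry with and without the mass: the sub-mass
        # promontory stratum must lose expected intensity
        scene = make_scene(preset, 13, grid_shape=small_grid)
        truth, _, _ = rasterize(scene)
        bare = dataclasses.replace(scene, class_preset="normal", mass=None)
        mu_mass = render_mean_intensity(scene)
        mu_bare = render_mean_intensity(bare)
        footprint = truth.mass_mask.any(axis=2)
        prom = truth.label_map == REGION_LABELS["promontory"]
        sel = prom & footprint[:, :, None]
        assert mu_mass[sel].mean() < mu_bare[sel].mean()


class TestSpeckleSampling:
    def test_zero_mean_gives_zero_intensity(self):
        assert np.all(sample_speckle_volume(np.zeros((3, 4, 5)), seed=0) == 0.0)

    def test_exponential_moments(self):
        c = 3.0
        vol = sample_speckle_volume(np.full((50, 60, 70), c), seed=42)
        assert vol.mean() == pytest.approx(c, rel=0.02)
        assert vol.var() == pytest.approx(c**2, rel=0.05)

    def test_exponential_goodness_of_fit(self):
        c = 1.7
        sample = sample_speckle_volume(np.full((400, 300), c), seed=7).ravel()
        assert sample.size >= 10**5
        stat = sps.kstest(sample, "expon", args=(0, c))
        assert stat.pvalue > 0.01

    def test_seed_determinism(self):
        mu = np.linspace(0, 2, 24).reshape(2, 3, 4)
        a = sample_speckle_volume(mu, seed=9)
        b = sample_speckle_volume(mu, seed=9)
        assert np.array_equal(a, b)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            sample_speckle_volume(np.array([-1.0]), seed=0)


class TestRepeatStacks:
    def test_static_tissue_without_noise_is_frozen(self):
        mu = np.full((30, 40), 2.0)
        stack = sample_repeat_stack(mu, np.ones_like(mu), 4, seed=3, noise_floor=0.0)
        for i in range(1, 4):
            np.testing.assert_array_equal(stack.data[i], stack.data[0])

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9, 1.0])
    def test_lag1_intensity_correlation_is_rho_squared(self, rho):
        # complex-Gaussian moment theorem: corr(I_i, I_{i+1}) = rho^2
        mu = np.full((320, 330), 1.5)
        stack = sample_repeat_stack(mu, np.full_like(mu, rho), 2,
                                    seed=int(rho * 10) + 50)
        i1, i2 = stack.data[0].ravel(), stack.data[1].ravel()
        assert i1.size >= 10**5
        corr = np.corrcoef(i1, i2)[0, 1]
        assert corr == pytest.approx(rho**2, abs=0.05)

    def test_iid_limit_matches_exponential_sampling(self):
        mu = np.full((200, 200), 2.5)
        stack = sample_repeat_stack(mu, np.zeros_like(mu), 3, seed=8)
        for frame in stack.data:
            assert frame.mean() == pytest.approx(2.5, rel=0.05)
        corr = np.corrcoef(stack.data[0].ravel(), stack.data[1].ravel())[0, 1]
        assert corr == pytest.approx(0.0, abs=0.05)

    def test_input_validation(self):
        mu = np.ones((4, 4))
        with pytest.raises(ValueError):
            sample_repeat_stack(mu, np.ones((3, 4)), 4, seed=0)
        with pytest.raises(ValueError):
            sample_repeat_stack(mu, np.ones_like(mu), 1, seed=0)
        with pytest.raises(ValueError):
            sample_repeat_stack(mu, np.full_like(mu, 1.5), 4, seed=0)


class TestCohort:
    def test_seeding_contract(self, tiny_grid):
        a = build_cohort([("normal", 2)], seed=5, grid_shape=tiny_grid,
                         with_stacks=False)
        b = build_cohort([("normal", 2)], seed=5, grid_shape=tiny_grid,
                         with_stacks=False)
        assert not np.array_equal(a[0].volume.data, a[1].volume.data)
        for ea, eb in zip(a, b):
            assert np.array_equal(ea.volume.data, eb.volume.data)

    def test_study_arm_bookkeeping(self, tiny_grid):
        cohort = build_cohort(
            [("normal", 6), ("glomus", 6), ("cholesteatoma", 4), ("schwannoma", 1)],
            seed=1, grid_shape=tiny_grid, with_stacks=False,
        )
        assert len(cohort) == 17
        labels = [e.class_label for e in cohort]
        assert labels.count("normal") == 6 and labels.count("glomus") == 6
        assert labels.count("cholesteatoma") == 4 and labels.count("schwannoma") == 1
        for ear in cohort:
            assert ear.truth.class_preset == ear.class_label

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            build_cohort([("polyp", 1)], seed=0)

    def test_repeat_stack_count_and_shape(self, tiny_grid):
        ear = build_ear("normal", 4, grid_shape=tiny_grid, n_repeats=3)
        ny, nx, nz = tiny_grid
        assert len(ear.stacks) == ny
        assert ear.stacks[0].data.shape == (3, nz, nx)
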