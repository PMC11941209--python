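"""ROI quantification, depth calibration, display rendering, gap measurement."""

import numpy as np
import pytest

from meoct import (
    DepthCalibration,
    Landmark,
    OCTVolume,
    RoiBox,
    angio_ratio,
    depth_uncertainty,
    enface_projection,
    extract_cross_sections,
    optical_to_physical_depth,
    render_display,
    roi_mean,
    structural_ratio,
    tumor_tm_gap,
)


class TestDepthCalibration:
    def test_air_path_is_identity(self):
        assert optical_to_physical_depth(1.0, "air") == 1.0

    def test_tissue_path_divided_by_1p4(self):
        assert optical_to_physical_depth(1.0, "tissue") == pytest.approx(1 / 1.4)
        assert round(optical_to_physical_depth(1.0, "tissue"), 3) == 0.714

    def test_zero_path(self):
        assert optical_to_physical_depth(0.0, "air") == 0.0
        assert optical_to_physical_depth(0.0, "tissue") == 0.0

    def test_negative_path_rejected(self):
        with pytest.raises(ValueError):
            optical_to_physical_depth(-0.1, "air")

    def test_unknown_medium_rejected(self):
        with pytest.raises(ValueError):
            optical_to_physical_depth(1.0, "bone")

    def test_uncertainty_collapsed_range_is_zero(self):
        cal = DepthCalibration(n_tissue=1.4, n_tissue_range=(1.4, 1.4))
        assert depth_uncertainty(cal)["max_abs"] == 0.0

    def test_uncertainty_bounds_at_range_endpoints(self):
        # n in [1.33, 1.45], assumed 1.4: signed bounds +5.3% / -3.4%
        u = depth_uncertainty(DepthCalibration())
        assert u["upper"] == pytest.approx(1.4 / 1.33 - 1, rel=1e-12)
        assert u["lower"] == pytest.approx(1.4 / 1.45 - 1, rel=1e-12)
        assert round(100 * u["upper"], 1) == 5.3
        assert round(100 * u["lower"], 1) == -3.4
        assert u["max_abs"] == pytest.approx(abs(u["upper"]))

    def test_uncertainty_monotone_in_range_width(self):
        narrow = depth_uncertainty(DepthCalibration(n_tissue_range=(1.38, 1.42)))
        wide = depth_uncertainty(DepthCalibration(n_tissue_range=(1.33, 1.45)))
        assert wide["max_abs"] >= narrow["max_abs"]

    def test_air_index_fixed(self):
        with pytest.raises(ValueError):
            DepthCalibration(n_air=1.1)


class TestRoiMean:
    def test_single_pixel_box(self):
        img = np.arange(12.0).reshape(3, 4)
        assert roi_mean(img, RoiBox(1, 2, 1, 1)) == img[1, 2]

    def test_hand_summed_2x2(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert roi_mean(img, RoiBox(0, 0, 2, 2)) == 2.5

    def test_constant_image_any_box(self):
        img = np.full((10, 10), 7.0)
        assert roi_mean(img, RoiBox(3, 4, 5, 2)) == 7.0

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            roi_mean(np.zeros((4, 4)), RoiBox(2, 2, 3, 3))


class TestRatios:
    def test_equal_intensity_gives_unity(self):
        img = np.full((20, 20), 5.0)
        res = structural_ratio(img, RoiBox(10, 0, 5, 5), RoiBox(0, 0, 5, 5))
        assert res.ratio == 1.0
        ares = angio_ratio(img, RoiBox(10, 0, 5, 5), RoiBox(0, 0, 5, 5))
        assert ares.ratio == 1.0 and ares.kind == "angio"

    def test_overlapping_boxes_rejected(self):
        img = np.ones((20, 20))
        with pytest.raises(ValueError):
            structural_ratio(img, RoiBox(0, 0, 5, 5), RoiBox(2, 2, 5, 5))

    def test_zero_reference_rejected(self):
        img = np.zeros((20, 20))
        img[10:, :] = 1.0
        with pytest.raises(ValueError):
            structural_ratio(img, RoiBox(10, 0, 5, 5), RoiBox(0, 0, 5, 5))

    def test_scale_invariance(self, rng):
        img = rng.random((30, 30)) + 0.1
        a, b = RoiBox(0, 0, 8, 8), RoiBox(15, 15, 8, 8)
        r1 = angio_ratio(img, a, b).ratio
        r2 = angio_ratio(img * 137.5, a, b).ratio
        assert r2 == pytest.approx(r1, rel=1e-12)


class TestCrossSections:
    def _volume(self, ny=6, nx=8, nz=10):
        data = np.broadcast_to(
            np.arange(ny, dtype=float)[:, None, None], (ny, nx, nz)
        ).copy()
        return OCTVolume(data=data)

    def test_xz_slice_is_constant_in_slow_value(self):
        vol = self._volume()
        xs = extract_cross_sections(vol, Landmark("umbo", (3, 4, 5)))
        assert np.all(xs.xz == 3.0)
        assert xs.xz.shape == (10, 8) and xs.yz.shape == (10, 6)
        assert xs.umbo_in_xz == (5, 4) and xs.umbo_in_yz == (5, 3)

    def test_corner_umbo_is_valid(self):
        vol = self._volume()
        xs = extract_cross_sections(vol, Landmark("umbo", (0, 0, 0)))
        assert xs.xz.shape == (10, 8)

    def test_out_of_bounds_umbo_rejected(self):
        with pytest.raises(ValueError):
            extract_cross_sections(self._volume(), Landmark("umbo", (6, 0, 0)))

    def test_wrong_landmark_rejected(self):
        with pytest.raises(ValueError):
            extract_cross_sections(
                self._volume(), Landmark("malleus_lateral_process", (0, 0, 0))
            )


class TestEnfaceProjection:
    def test_constant_volume(self):
        vol = OCTVolume(data=np.full((4, 5, 20), 3.0))
        assert np.all(enface_projection(vol, 2, 12) == 3.0)

    def test_ramp_gives_window_midpoint(self):
        data = np.broadcast_to(np.arange(20.0), (4, 5, 20)).copy()
        vol = OCTVolume(data=data)
        # arithmetic series mean over [4, 9) is (4+8)/2 = 6
        assert np.all(enface_projection(vol, 4, 9) == 6.0)

    def test_invalid_window_rejected(self):
        vol = OCTVolume(data=np.ones((4, 5, 20)))
        for lo, hi in [(5, 5), (9, 4), (-1, 5), (0, 21)]:
            with pytest.raises(ValueError):
                enface_projection(vol, lo, hi)


class TestRenderDisplay:
    def test_window_extremes(self):
        dr = 40.0
        i_max = 2.0
        img = np.array([[i_max, i_max * 10 ** (-dr / 10), i_max * 10 ** (-dr / 10 - 1)]])
        disp = render_display(img, dr)
        assert disp[0, 0] == 255
        assert disp[0, 1] == 0 and disp[0, 2] == 0

    def test_midpoint_closed_form(self):
        # I = Imax * 10^(-DR/20) maps to half range: 127.5, rounded half-up to 128
        dr = 30.0
        img = np.array([[1.0, 10 ** (-dr / 20)]])
        assert render_display(img, dr)[0, 1] == 128

    def test_deterministic_and_idempotent_in_effect(self, rng):
        vol = rng.random((4, 6, 8))
        a = render_display(vol, 35.0)
        b = render_display(vol.copy(), 35.0)
        assert a.dtype == np.uint8 and np.array_equal(a, b)

    def test_linear_scale_invariance(self, rng):
        # display depends on I / I_max only, so global gain cancels
        vol = rng.random((4, 6, 8)) + 0.01
        assert np.array_equal(render_display(vol, 30.0), render_display(vol * 42.0, 30.0))

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            render_display(np.ones((2, 2)), 0.0)
        with pytest.raises(ValueError):
            render_display(np.empty((0, 2)), 30.0)


class TestTumorTmGap:
    def test_touching_surfaces_give_zero(self):
        tm = np.full((4, 4), 10.0)
        gap = tumor_tm_gap(tm, tm.copy(), z_spacing_mm=0.02)
        assert gap.min_mm == 0.0 and gap.max_mm == 0.0 and gap.n_flagged == 0

    def test_air_conversion_is_identity(self):
        tm = np.full((3, 3), 5.0)
        mass = tm + 7.0
        gap = tumor_tm_gap(tm, mass, z_spacing_mm=0.02)
        assert gap.max_mm == pytest.approx(7 * 0.02)

    def test_inverted_lines_flagged_and_excluded(self):
        tm = np.full((2, 2), 10.0)
        mass = np.array([[12.0, 9.0], [11.0, 14.0]])
        gap = tumor_tm_gap(tm, mass, z_spacing_mm=0.1)
        assert gap.n_flagged == 1
        assert gap.min_mm == pytest.approx(0.1)
        assert gap.max_mm == pytest.approx(0.4)
        assert np.isnan(gap.gap_mm[0, 1])

    def test_footprint_from_nan_mass_surface(self):
        tm = np.full((2, 2), 3.0)
        mass = np.array([[np.nan, 5.0], [np.nan, 4.0]])
        gap = tumor_tm_gap(tm, mass, z_spacing_mm=1.0)
        assert gap.max_mm == 2.0 and np.isnan(gap.gap_mm[0, 0])
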