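import numpy as np
import pytest

from ctthermo import (
    ParameterError,
    PhantomConfig,
    RegistrationError,
    ThermoMap,
    VolumeScan,
    analytic_isotherm_radius,
    compute_map,
    display_threshold_k,
    measure_area,
    render_overlay,
    slope_sensitivity_sweep,
    synthesize_series,
)


def _pair(shape=(40, 40, 24), delta=0.0):
    pre = VolumeScan(grid=np.full(shape, 55.0), spacing=(1.0, 1.0, 1.0))
    peak = VolumeScan(grid=np.full(shape, 55.0 + delta), spacing=(1.0, 1.0, 1.0),
                      time_s=270.0, phase="peak")
    return pre, peak


CENTER = (19.5, 19.5, 11.5)


class TestDisplayThreshold:
    def test_necrosis_criterion_gives_33_k(self):
        """70 degC necrosis at a 37 degC core implies a 33 K map threshold."""
        assert display_threshold_k(70.0, 37.0) == 33.0

    def test_inverted_criterion_rejected(self):
        with pytest.raises(ParameterError):
            display_threshold_k(37.0, 70.0)


class TestComputeMap:
    def test_identical_scans_give_empty_map(self):
        pre, peak = _pair()
        tmap = compute_map(pre, peak, -1.96, CENTER, smoothing_fwhm_mm=0)
        assert np.all(tmap.delta_t == 0)
        assert not tmap.mask.any()
        assert tmap.area_mm2 == 0.0

    def test_uniform_delta_hu_at_exact_threshold(self):
        """ΔHU = −64.68 at slope −1.96 is ΔT = 33.0, included by >= rule."""
        pre, peak = _pair(delta=-64.68)
        tmap = compute_map(pre, peak, -1.96, CENTER, smoothing_fwhm_mm=0,
                           exclusion_radius_mm=0)
        assert np.allclose(tmap.delta_t, 33.0)
        assert tmap.mask.all()

    def test_positive_slope_rejected(self):
        pre, peak = _pair()
        with pytest.raises(ParameterError):
            compute_map(pre, peak, +1.96, CENTER)

    def test_mismatched_grids_rejected(self):
        pre, _ = _pair()
        _, peak = _pair(shape=(20, 20, 12))
        with pytest.raises(RegistrationError):
            compute_map(pre, peak, -1.96, CENTER)

    def test_linearity_of_delta_t_in_delta_hu(self):
        pre, peak1 = _pair(delta=-20.0)
        _, peak3 = _pair(delta=-60.0)
        m1 = compute_map(pre, peak1, -1.96, CENTER, smoothing_fwhm_mm=0,
                         exclusion_radius_mm=0)
        m3 = compute_map(pre, peak3, -1.96, CENTER, smoothing_fwhm_mm=0,
                         exclusion_radius_mm=0)
        assert np.allclose(m3.delta_t, 3.0 * m1.delta_t)

    @pytest.mark.parametrize("sigma_mm", [5.0, 10.0, 20.0])
    def test_mask_boundary_matches_analytic_isotherm(self, sigma_mm):
        """Mask radius equals the closed-form 33 K isotherm within a voxel."""
        cfg = PhantomConfig(shape=(96, 96, 24), noise_sd_hu=0, gas_enabled=False,
                            probe_radius_mm=0, motion_sd_mm=0, n_upslope=2,
                            n_post=0, sigma_mm_at_peak=sigma_mm)
        series, _, _ = synthesize_series(cfg)
        tmap = compute_map(series.pre, series.peak, cfg.true_slope,
                           tuple(cfg.tip), smoothing_fwhm_mm=0,
                           exclusion_radius_mm=0, probe_axis=tuple(cfg.axis))
        r_true = analytic_isotherm_radius(cfg, 70.0)
        r_measured = np.sqrt(tmap.area_mm2 / np.pi)
        assert abs(r_measured - r_true) <= max(cfg.spacing)
        # area within one voxel ring of the analytic disk
        ring = 2 * np.pi * r_true * max(cfg.spacing)
        assert abs(tmap.area_mm2 - np.pi * r_true ** 2) <= ring

    def test_probe_core_filled_and_flagged_unreliable(self):
        """Probe-corrupted voxels inside a hot zone join the mask via neighbours."""
        cfg = PhantomConfig(shape=(64, 64, 32), noise_sd_hu=0, gas_enabled=False,
                            probe_radius_mm=1.0, motion_sd_mm=0, n_upslope=2,
                            n_post=0, sigma_mm_at_peak=10.0)
        series, _, _ = synthesize_series(cfg)
        tmap = compute_map(series.pre, series.peak, cfg.true_slope,
                           tuple(cfg.tip), smoothing_fwhm_mm=0,
                           exclusion_radius_mm=8.0, probe_axis=tuple(cfg.axis))
        tip_idx = np.round(series.pre.world_to_index(cfg.tip)).astype(int)
        assert tmap.mask[tuple(tip_idx)]
        assert tmap.unreliable.any()
        assert not (tmap.unreliable & ~tmap.mask).any()


class TestMeasureArea:
    def _map_from_mask(self, mask, spacing=(1.0, 1.0, 1.0)):
        z = np.zeros(mask.shape)
        return ThermoMap(delta_hu=z, delta_t=z, mask=mask,
                         unreliable=np.zeros_like(mask), slope_used=-1.96,
                         threshold_k=33.0, core_temp_c=37.0,
                         spacing=spacing, origin=(0.0, 0.0, 0.0))

    def test_full_slice_area(self):
        mask = np.zeros((7, 9, 5), dtype=bool)
        mask[:, :, 2] = True
        tmap = self._map_from_mask(mask, spacing=(0.5, 2.0, 1.0))
        area, plane = measure_area(tmap, probe_tip=(0, 0, 0), probe_axis=(0, 0, 1))
        assert area == 7 * 9 * 0.5 * 2.0
        assert plane == 2

    def test_ball_mask_matches_circle_area(self):
        """Max cross-section of a voxelised ball: π r² within one voxel ring."""
        r = 9.0
        idx = np.indices((32, 32, 32)).transpose(1, 2, 3, 0)
        mask = np.linalg.norm(idx - 15.5, axis=-1) <= r
        tmap = self._map_from_mask(mask)
        area, plane = measure_area(tmap, probe_tip=(15.5, 15.5, 15.5))
        assert abs(area - np.pi * r ** 2) <= 2 * np.pi * r * 1.0
        # voxel counting can tie across central planes; the winner must be central
        assert plane in (14, 15, 16, 17)

    def test_area_equals_naive_voxel_count_loop(self):
        """Oracle: plane areas recomputed by an explicit triple loop."""
        rng = np.random.default_rng(7)
        mask = rng.random((12, 11, 10)) > 0.6
        tmap = self._map_from_mask(mask, spacing=(1.5, 0.5, 2.0))
        area, plane = measure_area(tmap, probe_tip=(0, 0, 0), probe_axis=(0, 0, 1))
        counts = [0] * 10
        for i in range(12):
            for j in range(11):
                for k in range(10):
                    if mask[i, j, k]:
                        counts[k] += 1
        assert area == max(counts) * 1.5 * 0.5
        assert plane == int(np.argmax(counts))

    def test_empty_mask_zero_area_at_tip_plane(self):
        tmap = self._map_from_mask(np.zeros((8, 8, 8), dtype=bool))
        area, plane = measure_area(tmap, probe_tip=(4.0, 4.0, 5.0))
        assert area == 0.0
        assert plane == 5


@pytest.fixture(scope="module")
def noisy_pair():
    cfg = PhantomConfig(shape=(72, 72, 32), noise_sd_hu=8.0, gas_enabled=False,
                        probe_radius_mm=1.0, motion_sd_mm=0, n_upslope=2,
                        n_post=0, sigma_mm_at_peak=10.0, seed=13)
    series, _, _ = synthesize_series(cfg)
    return cfg, series


class TestSlopeSweep:
    def test_area_nonincreasing_in_abs_slope(self, noisy_pair):
        """Same ΔHU maps to smaller ΔT at steeper slopes, shrinking the zone."""
        cfg, series = noisy_pair
        table = slope_sensitivity_sweep(
            series.pre, series.peak, [-0.5, -1.0, -1.5, -1.96], tuple(cfg.tip),
            probe_axis=tuple(cfg.axis), smoothing_fwhm_mm=0)
        areas = table["area_mm2"].to_numpy()
        assert len(table) == 4
        assert np.all(np.diff(areas) <= 0)

    def test_peripheral_artifacts_shrink_from_half_to_full_slope(self, noisy_pair):
        """Noise crosses the ΔT threshold far more easily at slope −0.5."""
        cfg, series = noisy_pair
        table = slope_sensitivity_sweep(
            series.pre, series.peak, [-0.5, -1.96], tuple(cfg.tip),
            probe_axis=tuple(cfg.axis), smoothing_fwhm_mm=0)
        artifacts = table.set_index("slope_hu_per_c")["artifact_voxels"]
        assert artifacts[-0.5] > artifacts[-1.96]

    def test_single_slope_consistent_with_compute_map(self, noisy_pair):
        cfg, series = noisy_pair
        table = slope_sensitivity_sweep(series.pre, series.peak, [-1.96],
                                        tuple(cfg.tip), probe_axis=tuple(cfg.axis),
                                        smoothing_fwhm_mm=0)
        tmap = compute_map(series.pre, series.peak, -1.96, tuple(cfg.tip),
                           probe_axis=tuple(cfg.axis), smoothing_fwhm_mm=0)
        assert table["area_mm2"].iloc[0] == tmap.area_mm2
        assert table["artifact_voxels"].iloc[0] == tmap.n_artifact_voxels


class TestOverlay:
    def test_empty_mask_renders_pure_grayscale(self):
        pre, peak = _pair()
        tmap = compute_map(pre, peak, -1.96, CENTER, smoothing_fwhm_mm=0)
        img = render_overlay(tmap, peak, plane_index=5)
        assert np.array_equal(img[..., 0], img[..., 1])
        assert np.array_equal(img[..., 0], img[..., 2])

    def test_red_pixel_count_equals_in_plane_mask_count(self, tmp_path):
        cfg = PhantomConfig(shape=(48, 48, 24), noise_sd_hu=0, gas_enabled=False,
                            probe_radius_mm=0, n_upslope=2, n_post=0)
        series, _, _ = synthesize_series(cfg)
        tmap = compute_map(series.pre, series.peak, cfg.true_slope, tuple(cfg.tip),
                           smoothing_fwhm_mm=0, exclusion_radius_mm=0)
        out = tmp_path / "overlay.png"
        img = render_overlay(tmap, series.peak, out_path=str(out))
        red = (img[..., 0].astype(int) - img[..., 1].astype(int)) > 0
        assert red.sum() == tmap.mask[:, :, tmap.area_plane_index].sum()
        assert out.exists()
        from PIL import Image
        assert np.array_equal(np.asarray(Image.open(out)), img)

    def test_full_slice_mask_tints_every_pixel(self):
        pre, peak = _pair(delta=-100.0)
        tmap = compute_map(pre, peak, -1.96, CENTER, smoothing_fwhm_mm=0,
                           exclusion_radius_mm=0)
        img = render_overlay(tmap, peak, plane_index=3)
        assert np.all(img[..., 0] > img[..., 1])

    def test_invalid_plane_rejected(self):
        pre, peak = _pair()
        tmap = compute_map(pre, peak, -1.96, CENTER, smoothing_fwhm_mm=0)
        with pytest.raises(ParameterError):
            render_overlay(tmap, peak, plane_index=99)
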