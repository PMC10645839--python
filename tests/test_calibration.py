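import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctthermo import (
    CircularROI,
    DegenerateInputError,
    MatchingError,
    TemperatureTrace,
    VolumeScan,
    fit_calibration,
    pair_hu_temperature,
    roi_mean_hu,
)
from ctthermo.phantom import synthesize_calibration_pairs


def _uniform_scan(value=55.0, shape=(32, 32, 20)):
    return VolumeScan(grid=np.full(shape, value), spacing=(1.0, 1.0, 1.0))


class TestRoiMean:
    def test_uniform_slab_mean_exact(self):
        roi = CircularROI(center=(15.5, 15.5, 9.5), diameter_mm=20.0)
        out = roi_mean_hu(_uniform_scan(), roi)
        assert out.mean_hu == 55.0
        assert out.n_excluded == 0

    def test_probe_voxels_excluded_from_mean(self):
        """Hyperdense probe voxels above the threshold drop out entirely."""
        scan = _uniform_scan()
        scan.grid[14:17, 14:17, :] = 3000.0
        roi = CircularROI(center=(15.5, 15.5, 9.5), diameter_mm=20.0)
        out = roi_mean_hu(scan, roi, exclude_above_hu=1000.0)
        assert out.mean_hu == 55.0
        assert out.n_excluded > 0

    def test_all_voxels_excluded_raises(self):
        scan = _uniform_scan(3000.0)
        roi = CircularROI(center=(15.5, 15.5, 9.5), diameter_mm=10.0)
        with pytest.raises(DegenerateInputError):
            roi_mean_hu(scan, roi, exclude_above_hu=1000.0)

    def test_roi_outside_grid_raises(self):
        roi = CircularROI(center=(500.0, 500.0, 500.0), diameter_mm=5.0)
        with pytest.raises(DegenerateInputError):
            roi_mean_hu(_uniform_scan(), roi)

    def test_peak_scan_mean_matches_disk_integral_oracle(self, noiseless_case):
        """ROI mean on the clean peak scan vs. numerical disk integration."""
        cfg, series, _, _ = noiseless_case
        radius = 15.0
        roi = CircularROI(center=tuple(cfg.tip), diameter_mm=2 * radius,
                          plane_normal=tuple(cfg.axis))
        got = roi_mean_hu(series.peak, roi, slab_mm=cfg.spacing[2]).mean_hu
        # independent oracle: fine polar quadrature of the Gaussian profile
        r = np.linspace(0, radius, 2001)[1:]
        profile = cfg.baseline_hu + cfg.true_slope * cfg.peak_delta_t_c * np.exp(
            -(r ** 2) / (2 * cfg.sigma_mm_at_peak ** 2))
        oracle = np.sum(profile * r) / np.sum(r)  # area-weighted mean
        assert got == pytest.approx(oracle, abs=0.5)


class TestPairing:
    def _trace(self, times, temps):
        df = pd.DataFrame({"time_s": list(times) * 2,
                           "sensor_id": ["hot"] * len(times) + ["cold"] * len(times),
                           "temperature_c": list(temps) + [t - 10 for t in temps]})
        return TemperatureTrace(ablation_id="phantom-A", samples=df)

    def test_ten_upslope_scans_give_ten_pairs(self, full_noiseless_case):
        cfg, series, trace, _ = full_noiseless_case
        roi = CircularROI(center=tuple(cfg.tip), diameter_mm=20.0,
                          plane_normal=tuple(cfg.axis))
        pairs = pair_hu_temperature(series, trace, roi)
        assert len(pairs) == 10  # pre + 8 upslope + peak

    def test_empty_trace_raises_matching_error(self, full_noiseless_case):
        cfg, series, _, _ = full_noiseless_case
        roi = CircularROI(center=tuple(cfg.tip), diameter_mm=20.0)
        empty = TemperatureTrace(ablation_id="phantom-A", samples=pd.DataFrame(
            {"time_s": [], "sensor_id": [], "temperature_c": []}))
        with pytest.raises(MatchingError):
            pair_hu_temperature(series, empty, roi)

    def test_hotter_sensor_selected(self, full_noiseless_case):
        cfg, series, _, _ = full_noiseless_case
        roi = CircularROI(center=tuple(cfg.tip), diameter_mm=20.0,
                          plane_normal=tuple(cfg.axis))
        times = [s.time_s for s in series.scans]
        trace = self._trace(times, np.linspace(37, 90, len(times)))
        pairs = pair_hu_temperature(series, trace, roi)
        expected = np.linspace(37, 90, len(times))[:10]
        assert np.allclose(pairs["temperature_c"], expected)

    def test_phantom_pairs_monotone_hu_down_t_up(self, full_noiseless_case):
        """Noiseless upslope: HU strictly falls while T strictly rises."""
        cfg, series, trace, _ = full_noiseless_case
        roi = CircularROI(center=tuple(cfg.tip), diameter_mm=20.0,
                          plane_normal=tuple(cfg.axis))
        pairs = pair_hu_temperature(series, trace, roi)
        hu = pairs["mean_hu"].to_numpy()
        temp = pairs["temperature_c"].to_numpy()
        assert np.all(np.diff(hu) < 0)
        assert np.all(np.diff(temp) > 0)


class TestFitCalibration:
    def test_exact_linear_data_recovered(self):
        temps = np.linspace(37, 90, 12)
        pairs = pd.DataFrame({"mean_hu": 150.0 - 2.0 * temps,
                              "temperature_c": temps})
        fit = fit_calibration(pairs)
        assert fit.slope_hu_per_c == pytest.approx(-2.0, abs=1e-10)
        assert fit.intercept_hu == pytest.approx(150.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.spearman_r == -1.0

    def test_spearman_minus_one_for_any_strictly_decreasing_map(self):
        temps = np.linspace(37, 90, 15)
        pairs = pd.DataFrame({"mean_hu": 1000.0 / temps,  # nonlinear, decreasing
                              "temperature_c": temps})
        assert fit_calibration(pairs).spearman_r == -1.0

    def test_permuted_hu_gives_null_result(self, rng):
        temps = np.repeat(np.linspace(37, 90, 10), 3)
        hu = rng.permutation(np.linspace(-60, 55, 30))
        fit = fit_calibration(pd.DataFrame({"mean_hu": hu, "temperature_c": temps}))
        assert abs(fit.spearman_r) < 0.5
        assert fit.slope_ci[0] <= 0.0 <= fit.slope_ci[1]

    def test_zero_temperature_variance_rejected(self):
        pairs = pd.DataFrame({"mean_hu": [1.0, 2.0, 3.0],
                              "temperature_c": [37.0, 37.0, 37.0]})
        with pytest.raises(DegenerateInputError):
            fit_calibration(pairs)

    def test_slope_invariant_to_hu_offset(self, rng):
        pairs = synthesize_calibration_pairs(rng)
        fit = fit_calibration(pairs)
        shifted = pairs.assign(mean_hu=pairs["mean_hu"] + 500.0)
        fit2 = fit_calibration(shifted)
        assert fit2.slope_hu_per_c == pytest.approx(fit.slope_hu_per_c, abs=1e-9)
        assert fit2.intercept_hu == pytest.approx(fit.intercept_hu + 500.0, abs=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_spearman_invariant_under_monotone_transforms(self, seed):
        """Rank correlation ignores any strictly monotone reparametrisation."""
        rng = np.random.default_rng(seed)
        pairs = synthesize_calibration_pairs(rng, n_ablations=1, n_timepoints=12)
        base = fit_calibration(pairs).spearman_r
        warped = pairs.assign(
            mean_hu=np.exp(pairs["mean_hu"] / 50.0),
            temperature_c=pairs["temperature_c"] ** 3,
        )
        assert fit_calibration(warped).spearman_r == pytest.approx(base, abs=1e-12)

    def test_ci_coverage_of_true_slope(self):
        """95% slope CI covers the generating slope at a near-nominal rate."""
        from scipy.stats import binomtest
        covered = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            pairs = synthesize_calibration_pairs(rng, noise_sd_hu=8.0, slope=-1.96)
            fit = fit_calibration(pairs)
            if fit.slope_ci[0] <= -1.96 <= fit.slope_ci[1]:
                covered += 1
        assert covered >= 93
        assert binomtest(covered, n_rep, 0.95).pvalue > 0.01
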