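"""Outlier filtering and background correction."""

import numpy as np
import pytest

import wellinvert as wi
from wellinvert.preprocess import (
    BackgroundSpec,
    OutlierFilterParams,
    SavitzkyGolayOutlierFilter,
    apply_background_correction,
    build_calibration_curve,
    detect_outliers_auto,
    detect_outliers_band,
    sg_smooth,
)

from conftest import make_series


class TestSgSmooth:
    def test_reproduces_low_order_polynomial(self):
        t = np.arange(40.0)
        v = 2.0 + 0.3 * t - 0.01 * t**2
        out = sg_smooth(make_series(t, v), window=15, polyorder=3)
        np.testing.assert_allclose(out, v, atol=1e-10)

    def test_constant_series_unchanged(self):
        t = np.arange(30.0)
        out = sg_smooth(make_series(t, np.full(30, 5.0)), window=11, polyorder=2)
        np.testing.assert_allclose(out, 5.0, atol=1e-12)

    def test_reduces_noise_variance(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 4 * np.pi, 200)
        clean = np.sin(t)
        noisy = clean + rng.normal(0, 0.2, t.size)
        smooth = sg_smooth(make_series(t, noisy), window=15, polyorder=3)
        assert np.var(smooth - clean) < np.var(noisy - clean)

    def test_masked_points_interpolated(self):
        t = np.arange(30.0)
        v = 1.0 + 0.5 * t
        v[10] = 100.0  # spike, masked out
        mask = np.zeros(30, bool)
        mask[10] = True
        out = sg_smooth(make_series(t, v, outlier_mask=mask), window=11, polyorder=2)
        assert abs(out[10] - (1.0 + 0.5 * 10)) < 1e-8

    @pytest.mark.parametrize("window,polyorder", [(10, 3), (5, 5), (5, 7)])
    def test_bad_window_rejected(self, window, polyorder):
        t = np.arange(30.0)
        with pytest.raises(ValueError, match="window"):
            sg_smooth(make_series(t, t), window=window, polyorder=polyorder)


class TestAutoOutliers:
    def test_clean_exponential_unflagged(self):
        t = np.arange(0, 300, 2.0)
        series = make_series(t, 0.05 * np.exp(0.01 * t))
        assert not detect_outliers_auto(series).any()

    def test_injected_spikes_all_found_no_false_positives(self):
        rng = np.random.default_rng(42)
        t = np.arange(0, 400, 2.0)
        v = 0.05 * np.exp(0.008 * t) + rng.normal(0, 0.01, t.size)
        spike_idx = np.array([20, 60, 110, 150, 190])
        v[spike_idx] += 8 * 0.01 * np.array([1, -1, 1, 1, -1])
        params = OutlierFilterParams(cutoff_sigma=4.0)
        mask = detect_outliers_auto(make_series(t, v), params)
        assert set(np.nonzero(mask)[0]) == set(spike_idx)

    def test_bead_spike_pattern_from_simulator(self):
        truth = wi.scenario_constitutive(
            0.0125, 500.0, outlier_rate=0.04, outlier_amplitude=8.0, seed=5
        )
        exp, record = wi.simulate_experiment(truth, 1)
        series = exp.get_series("A5", "absorbance")
        mask = detect_outliers_auto(series)
        injected = set(record["outliers"]["A5"]["absorbance"].tolist())
        flagged = set(np.nonzero(mask)[0].tolist())
        assert injected, "fixture should contain spikes"
        assert len(injected & flagged) / len(injected) >= 0.9
        assert len(flagged - injected) <= 0.05 * (len(series) - len(injected))

    def test_idempotent_once_converged(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 400, 2.0)
        v = 0.05 * np.exp(0.008 * t) + rng.normal(0, 0.01, t.size)
        v[[30, 90]] += 0.15
        params = OutlierFilterParams(iterations=10)
        series = make_series(t, v)
        mask1 = detect_outliers_auto(series, params)
        mask2 = detect_outliers_auto(series.replace(outlier_mask=mask1), params)
        np.testing.assert_array_equal(mask1, mask2)

    def test_mask_is_monotone(self):
        rng = np.random.default_rng(2)
        t = np.arange(0, 400, 2.0)
        v = 0.05 * np.exp(0.008 * t) + rng.normal(0, 0.01, t.size)
        existing = np.zeros(t.size, bool)
        existing[17] = True
        mask = detect_outliers_auto(make_series(t, v, outlier_mask=existing))
        assert mask[17]

    def test_short_series_error(self):
        with pytest.raises(ValueError, match="window"):
            detect_outliers_auto(make_series(np.arange(5.0), np.ones(5)))

    def test_sklearn_estimator_interface(self):
        from sklearn.base import clone

        t = np.arange(0, 400, 2.0)
        rng = np.random.default_rng(3)
        v = 0.05 * np.exp(0.008 * t) + rng.normal(0, 0.01, t.size)
        v[50] += 0.2
        est = SavitzkyGolayOutlierFilter(cutoff_sigma=4.0)
        assert clone(est).get_params()["cutoff_sigma"] == 4.0
        mask = est.fit(t.reshape(-1, 1), v).predict()
        assert mask[50]
        assert est.smoothed_.shape == t.shape


class TestBandOutliers:
    def test_infinite_tolerance_empty_mask(self):
        t = np.arange(10.0)
        mask = detect_outliers_band(make_series(t, t**2), [(0, 0), (9, 81)], np.inf)
        assert not mask.any()

    def test_boundary_inclusive(self):
        t = np.arange(5.0)
        v = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        mask = detect_outliers_band(make_series(t, v), [(0, 0), (4, 4)], tolerance=0.0)
        assert not mask.any()

    def test_single_displaced_point_flagged(self):
        t = np.arange(10.0)
        v = t.copy()
        v[4] += 2.0
        mask = detect_outliers_band(make_series(t, v), [(0, 0), (9, 9)], tolerance=1.0)
        assert list(np.nonzero(mask)[0]) == [4]

    def test_bad_anchors_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError, match="anchor"):
            detect_outliers_band(make_series(t, t), [(5, 0), (1, 1)], 1.0)
        with pytest.raises(ValueError, match="anchor"):
            detect_outliers_band(make_series(t, t), [(0, 0)], 1.0)


class TestCalibrationCurve:
    @staticmethod
    def _linear_bg(n=50):
        t = np.arange(float(n))
        a = np.linspace(0.01, 0.5, n)
        f = 2 * a + 1
        return (make_series(t, a), make_series(t, f))

    def test_reproduces_linear_relation(self):
        sa, sf = self._linear_bg()
        curve = build_calibration_curve(sa, sf, smoothing=0.5)
        aa = np.linspace(0.01, 0.5, 31)
        np.testing.assert_allclose(curve(aa), 2 * aa + 1, atol=1e-6)

    def test_extrapolation_uses_boundary_slope(self):
        sa, sf = self._linear_bg()
        curve = build_calibration_curve(
            sa, sf, smoothing=0.5, extrapolation_interval=(0.0, 0.8)
        )
        hi = curve.support[1]
        slope = (curve(hi) - curve(hi - 1e-6)) / 1e-6
        delta = 0.1
        assert curve(hi + delta) == pytest.approx(curve(hi) + slope * delta, rel=1e-4)

    def test_continuous_across_boundary_and_clamped_outside(self):
        sa, sf = self._linear_bg()
        curve = build_calibration_curve(
            sa, sf, smoothing=0.5, extrapolation_interval=(0.0, 0.6)
        )
        hi = curve.support[1]
        assert curve(hi + 1e-9) == pytest.approx(curve(hi), abs=1e-6)
        # beyond the extrapolation interval the boundary value is held
        no_extra = build_calibration_curve(sa, sf, smoothing=0.5)
        assert no_extra(5.0) == pytest.approx(no_extra(hi), abs=1e-9)

    def test_too_few_pairs_rejected(self):
        t = np.arange(4.0)
        sa = make_series(t, np.linspace(0.1, 0.4, 4))
        sf = make_series(t, np.linspace(1, 2, 4))
        with pytest.raises(ValueError, match=">= 5"):
            build_calibration_curve(sa, sf)

    def test_mismatched_timestamps_rejected(self):
        sa = make_series(np.arange(10.0), np.linspace(0.1, 0.4, 10))
        sf = make_series(np.arange(10.0) + 100, np.linspace(1, 2, 10))
        with pytest.raises(ValueError, match="shared"):
            build_calibration_curve(sa, sf)


class TestBackgroundCorrection:
    def test_fixed_baseline_default_value(self):
        t = np.arange(10.0)
        v = np.linspace(0.1, 1.0, 10)
        out = apply_background_correction(
            make_series(t, v), BackgroundSpec(method="fixed", baseline=0.084)
        )
        np.testing.assert_allclose(out.corrected_values, v - 0.084)
        np.testing.assert_array_equal(out.values, v)  # raw untouched

    def test_series_minus_own_background_is_zero(self):
        t = np.arange(10.0)
        v = np.linspace(1, 2, 10)
        series = make_series(t, v)
        out = apply_background_correction(
            series, BackgroundSpec(method="background_well", background_series=series)
        )
        np.testing.assert_allclose(out.corrected_values, 0.0, atol=1e-12)

    def test_background_well_must_cover_range(self):
        series = make_series(np.arange(10.0), np.ones(10))
        bg = make_series(np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError, match="cover"):
            apply_background_correction(
                series, BackgroundSpec(method="background_well", background_series=bg)
            )

    def test_fixed_correction_is_linear(self):
        t = np.arange(20.0)
        rng = np.random.default_rng(0)
        v1, v2 = rng.random(20), rng.random(20)
        spec = BackgroundSpec(method="fixed", baseline=0.3)
        both = apply_background_correction(make_series(t, v1 + v2), spec)
        one = apply_background_correction(make_series(t, v1), spec)
        np.testing.assert_allclose(both.corrected_values, one.corrected_values + v2)

    def test_spec_field_consistency_enforced(self):
        with pytest.raises(ValueError, match="requires"):
            BackgroundSpec(method="fixed").validate()
        with pytest.raises(ValueError, match="must not set"):
            BackgroundSpec(method="fixed", baseline=0.1,
                           background_series=make_series([0, 1], [1, 1])).validate()

    def test_calibration_removes_growth_dependent_autofluorescence(self):
        truth = wi.scenario_constitutive(0.0125, 500.0, seed=3)
        exp, record = wi.simulate_experiment(truth, 1, include_background_well=True)
        fixed = BackgroundSpec(method="fixed", baseline=truth.abs_background)
        bg_abs = apply_background_correction(exp.get_series("A3", "absorbance"), fixed)
        sig_abs = apply_background_correction(exp.get_series("A5", "absorbance"), fixed)
        curve = build_calibration_curve(
            bg_abs, exp.get_series("A3", "fluorescence:gfp"), smoothing=0.1
        )
        corrected = apply_background_correction(
            exp.get_series("A5", "fluorescence:gfp"),
            BackgroundSpec(method="calibration", curve=curve),
            paired_absorbance=sig_abs,
        )
        err = corrected.corrected_values - record["betaR"]
        rms_rel = np.sqrt(np.mean(err**2)) / np.sqrt(np.mean(record["betaR"] ** 2))
        assert rms_rel <= 0.02

    def test_calibration_requires_pairing(self):
        sa, sf = TestCalibrationCurve._linear_bg()
        curve = build_calibration_curve(sa, sf, smoothing=0.5)
        with pytest.raises(ValueError, match="paired_absorbance"):
            apply_background_correction(
                sf, BackgroundSpec(method="calibration", curve=curve)
            )
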