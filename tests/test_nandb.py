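"""Number & brightness: calibration, detrending, brightness maps and
oligomer-class partitioning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nanodomain import (
    DetectorCalibration,
    brightness_map,
    calibrate_detector,
    detrend_series,
    oligomer_calibration_curve,
    partition_brightness,
    simulate_nandb_stack,
)
from nanodomain.exceptions import CalibrationError, ParameterError
from nanodomain.simulate import DetectorModel


class TestCalibration:
    def test_photon_counting_gives_identity(self):
        series = [
            simulate_nandb_stack(n_frames=50, shape=(32, 64), epsilon=e,
                                 mode="immobile", seed=i)
            for i, e in enumerate((0.2, 0.5, 1.0, 2.0))
        ]
        cal = calibrate_detector(series)
        assert cal.gain_s == pytest.approx(1.0, rel=0.03)
        assert abs(cal.offset) < 0.05

    def test_analog_gain_recovery(self):
        det = DetectorModel(mode="analog", gain_s=30.0, offset=100.0, sigma0=0.05)
        series = [
            simulate_nandb_stack(n_frames=50, shape=(32, 64), epsilon=e,
                                 detector=det, mode="immobile", seed=i)
            for i, e in enumerate((0.1, 0.2, 0.4, 0.8))
        ]
        rng = np.random.default_rng(9)
        dark = det.offset + rng.normal(0, det.sigma0, size=(50, 32, 64))
        cal = calibrate_detector(series, dark_series=dark)
        assert cal.gain_s == pytest.approx(30.0, rel=0.05)
        assert cal.offset == pytest.approx(100.0, rel=0.05)
        assert cal.sigma0 == 0.0  # below the 0.1 zero-approximation threshold
        assert cal.r_value >= 0.99

    def test_wide_dark_noise_estimated_from_histogram(self):
        rng = np.random.default_rng(3)
        det = DetectorModel(mode="analog", gain_s=10.0, offset=0.0, sigma0=0.0)
        series = [
            simulate_nandb_stack(n_frames=50, shape=(32, 64), epsilon=e,
                                 detector=det, mode="immobile", seed=i)
            for i, e in enumerate((0.5, 1.0, 2.0))
        ]
        dark = rng.normal(0.0, 3.0, size=(100, 64, 64))
        cal = calibrate_detector(series, dark_series=dark)
        assert cal.sigma0 == pytest.approx(3.0, rel=0.2)

    def test_nonlinear_response_rejected(self):
        rng = np.random.default_rng(7)
        series = []
        for mean, sd in ((1.0, 1.0), (2.0, 3.0), (3.0, 1.0)):
            series.append(rng.normal(mean, sd, size=(50, 16, 16)))
        with pytest.raises(CalibrationError):
            calibrate_detector(series)

    def test_needs_three_power_levels(self):
        with pytest.raises(ParameterError):
            calibrate_detector([np.zeros((10, 4, 4))] * 2)


class TestDetrend:
    def test_constant_series_unchanged(self):
        stack = np.full((50, 8, 8), 7.0)
        np.testing.assert_array_equal(detrend_series(stack, 10), stack)

    def test_mean_preserved_exactly(self):
        rng = np.random.default_rng(1)
        stack = rng.poisson(5.0, size=(50, 16, 16)).astype(float)
        out = detrend_series(stack, 10)
        np.testing.assert_allclose(out.mean(axis=0), stack.mean(axis=0), rtol=1e-12)

    def test_white_noise_variance_preserved(self):
        rng = np.random.default_rng(2)
        stack = rng.normal(10.0, 1.0, size=(50, 64, 64))
        out = detrend_series(stack, 10)
        ratio = out.var(axis=0, ddof=1).mean() / stack.var(axis=0, ddof=1).mean()
        assert abs(ratio - 1.0) < 0.05

    def test_removes_slow_trend(self):
        t = np.arange(50, dtype=float)
        trend = (1.0 - 0.004 * t)[:, None, None] * np.ones((50, 4, 4)) * 100.0
        out = detrend_series(trend, 10)
        # residual variance of the pure trend is tiny after high-passing
        assert out.var(axis=0, ddof=1).mean() < 0.05 * trend.var(axis=0, ddof=1).mean()

    def test_bleached_series_matches_unbleached_brightness(self):
        b0 = brightness_map(
            simulate_nandb_stack(seed=1, epsilon=0.2), detrend_window=10
        ).mean_b()
        bb = brightness_map(
            simulate_nandb_stack(seed=1, epsilon=0.2, bleach_rate_per_frame=0.004),
            detrend_window=10,
        ).mean_b()
        assert abs(bb - b0) / b0 < 0.02

    def test_window_bounds(self):
        stack = np.zeros((10, 4, 4))
        with pytest.raises(ParameterError):
            detrend_series(stack, 1)
        with pytest.raises(ParameterError):
            detrend_series(stack, 10)


class TestBrightnessMap:
    def test_immobile_pixels_have_unit_brightness(self):
        stack = simulate_nandb_stack(
            n_frames=100, shape=(64, 128), epsilon=0.5, mode="immobile", seed=4
        )
        bm = brightness_map(stack, detrend_window=10)
        assert bm.mean_b() == pytest.approx(1.0, abs=0.01)

    def test_monomer_condition_recovers_reported_brightness(self):
        stack = simulate_nandb_stack(
            n_frames=50, shape=(64, 256), epsilon=0.21, seed=0
        )
        bm = brightness_map(stack, detrend_window=10)
        assert bm.mean_b() == pytest.approx(1.21, abs=0.02)

    def test_mixture_brightness_intensity_weighted(self):
        eps = 0.3
        stack = simulate_nandb_stack(
            n_frames=200, shape=(64, 128), epsilon=eps, oligomer_mix=(0.5, 0.5),
            seed=5,
        )
        bm = brightness_map(stack, detrend_window=20)
        expected = 1 + eps * (0.5 + 2.0) / 1.5
        assert bm.mean_b() == pytest.approx(expected, abs=0.02)

    def test_low_intensity_pixels_masked(self):
        stack = simulate_nandb_stack(n_frames=50, shape=(16, 16), epsilon=0.2, seed=6)
        calib = DetectorCalibration(gain_s=1.0, offset=1.0e6, sigma0=0.0)
        with pytest.raises(ParameterError):
            # every pixel mean <= offset -> nothing defined
            brightness_map(stack, calib).mean_b()

    def test_brightness_monotone_in_oligomer_order(self):
        means = []
        for n_mer in (1, 2, 3):
            mix = tuple(0.0 for _ in range(n_mer - 1)) + (1.0,)
            stack = simulate_nandb_stack(
                n_frames=100, shape=(64, 64), epsilon=0.1, oligomer_mix=mix, seed=n_mer
            )
            means.append(brightness_map(stack, detrend_window=10).mean_b())
        assert means[0] < means[1] < means[2]


class TestOligomerCurve:
    def test_exact_linear_arithmetic(self):
        curve = oligomer_calibration_curve(1.1, 1.2, 1.3)
        assert curve.slope == pytest.approx(0.1)
        assert curve.predicted_b(6) == pytest.approx(1.6)
        assert curve.class_boundaries[0] == pytest.approx(1.15)
        assert curve.class_centers.size == 6

    def test_simulated_references_recover_slope(self):
        bs = []
        for n_mer in (1, 2, 3):
            mix = tuple(0.0 for _ in range(n_mer - 1)) + (1.0,)
            stack = simulate_nandb_stack(
                n_frames=200, shape=(64, 64), epsilon=0.1, oligomer_mix=mix,
                seed=40 + n_mer,
            )
            bs.append(brightness_map(stack, detrend_window=20).mean_b())
        curve = oligomer_calibration_curve(*bs)
        assert curve.slope == pytest.approx(0.1, rel=0.1)

    def test_non_monotone_rejected(self):
        with pytest.raises(ParameterError):
            oligomer_calibration_curve(1.2, 1.1, 1.3)

    @given(
        b1=st.floats(1.01, 1.2), step=st.floats(0.05, 0.3)
    )
    def test_boundaries_interleave_centers(self, b1, step):
        curve = oligomer_calibration_curve(b1, b1 + step, b1 + 2 * step)
        c = curve.class_centers
        b = curve.class_boundaries
        assert np.all((b > c[:-1]) & (b < c[1:]))


class TestPartition:
    @staticmethod
    def _bmap(values: np.ndarray):
        from nanodomain.nandb import BrightnessMap

        return BrightnessMap(
            b=values.astype(float), mean_intensity=np.ones_like(values, dtype=float),
            n_frames=50, detrend_window=10,
        )

    def test_degenerate_single_value_goes_to_one_class(self):
        curve = oligomer_calibration_curve(1.1, 1.2, 1.3)
        pct = partition_brightness(self._bmap(np.full((4, 4), 1.1)), curve)
        assert pct[0] == 100.0
        assert pct.sum() == pytest.approx(100.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(11)
        curve = oligomer_calibration_curve(1.1, 1.2, 1.3)
        pct = partition_brightness(self._bmap(rng.normal(1.3, 0.15, (32, 32))), curve)
        assert pct.sum() == pytest.approx(100.0)
        assert pct.size == 6

    def test_mixture_recovery(self):
        """70% monomer / 30% tetramer pixel population recovered within 10
        percentage points (monomer vs higher-order split)."""
        rng = np.random.default_rng(12)
        n = 4000
        b = np.concatenate([
            rng.normal(1.1, 0.02, int(0.7 * n)),
            rng.normal(1.4, 0.02, n - int(0.7 * n)),
        ])
        curve = oligomer_calibration_curve(1.1, 1.2, 1.3)
        pct = partition_brightness(self._bmap(b.reshape(40, -1)), curve)
        assert abs(pct[0] - 70.0) < 10.0
        assert abs(pct[3] - 30.0) < 10.0

    def test_needs_enough_pixels(self):
        curve = oligomer_calibration_curve(1.1, 1.2, 1.3)
        with pytest.raises(ParameterError):
            partition_brightness(self._bmap(np.array([[1.1, 1.2]])), curve)
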