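"""Intensity traces, spline smoothing, and expression-rate estimation."""

import numpy as np
import pytest

from colonylapse import (
    GrowthModelFit,
    IntensityTrace,
    Timelapse,
    expression_rate,
    intensity_series,
    smooth_trace,
)
from colonylapse.detect import SquareROI
from colonylapse.expression import circle_mask


def _flat_fit(Amax=1000.0, mu_max=0.5, t0=5.0, colony_id=0):
    return GrowthModelFit(
        colony_id=colony_id, Amax=Amax, mu_max=mu_max, t0=t0,
        residual_rms=0.0, n_points_used=10,
    )


def _trace(times, values, colony_id=0):
    n = np.full(len(times), 10.0)
    values = np.asarray(values, dtype=float)
    return IntensityTrace(
        colony_id=colony_id, times=np.asarray(times, float),
        total_I=values * n, n_pixels=n, mean_F=values,
    )


class TestIntensitySeries:
    def test_uniform_disc_totals(self):
        """Every pixel with all channels = v inside a mask of n pixels
        gives total 3 v n and mean 3 v."""
        frames = np.full((3, 40, 40, 3), 7.0)
        stack = Timelapse(frames=frames, times=np.arange(3.0))
        roi = SquareROI(0, (20.0, 20.0), 15, (5, 36), (5, 36))
        fit = _flat_fit(Amax=200.0, mu_max=0.5, t0=-50.0)  # radius ~ plateau
        trace = intensity_series(stack, roi, fit, (20.0, 20.0))
        expected_n = circle_mask((31, 31), (15.0, 15.0), fit.radius(0.0)).sum()
        np.testing.assert_allclose(trace.n_pixels, expected_n)
        np.testing.assert_allclose(trace.total_I, 3 * 7.0 * expected_n)
        np.testing.assert_allclose(trace.mean_F, 21.0)

    def test_zero_stack_zero_mean(self):
        stack = Timelapse(frames=np.zeros((3, 30, 30, 3)), times=np.arange(3.0))
        roi = SquareROI(0, (15.0, 15.0), 10, (5, 26), (5, 26))
        trace = intensity_series(stack, roi, _flat_fit(t0=-50.0), (15.0, 15.0))
        assert np.all(trace.mean_F[trace.n_pixels > 0] == 0.0)

    def test_matches_pixel_loop_oracle(self, single_colony_plate, single_colony_roi):
        """Vectorized masked sums equal an explicit per-pixel loop."""
        corrected, _, _ = single_colony_plate
        sub = Timelapse(
            frames=corrected.frames[:5], times=corrected.times[:5],
            background=corrected.background,
        )
        fit = _flat_fit(Amax=900.0, mu_max=0.5, t0=1.0)
        trace = intensity_series(sub, single_colony_roi, fit, (60.0, 60.0))

        roi = single_colony_roi
        for t in range(5):
            radius = fit.radius(sub.times[t])
            total = 0.0
            n = 0
            for r in range(roi.row_range[0], roi.row_range[1]):
                for c in range(roi.col_range[0], roi.col_range[1]):
                    if (r - 60.0) ** 2 + (c - 60.0) ** 2 <= radius**2:
                        n += 1
                        for ch in range(3):
                            total += sub.frames[t, r, c, ch]
            assert trace.n_pixels[t] == n
            assert trace.total_I[t] == total

    def test_linearity_in_intensity(self, single_colony_plate, single_colony_roi):
        corrected, _, _ = single_colony_plate
        doubled = Timelapse(frames=2.0 * corrected.frames, times=corrected.times)
        fit = _flat_fit(Amax=900.0, mu_max=0.5, t0=12.0)
        t1 = intensity_series(corrected, single_colony_roi, fit, (60.0, 60.0))
        t2 = intensity_series(doubled, single_colony_roi, fit, (60.0, 60.0))
        np.testing.assert_allclose(t2.mean_F, 2.0 * t1.mean_F)


class TestSmoothTrace:
    def test_interpolating_limit(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 10, 20)
        f = rng.uniform(5, 50, 20)
        smoothed = smooth_trace(_trace(t, f), smoothing_factor=0.0)
        np.testing.assert_allclose(smoothed(t), f, atol=1e-9)

    def test_linear_derivative(self):
        t = np.linspace(0, 10, 25)
        smoothed = smooth_trace(_trace(t, 2.0 * t), smoothing_factor=0.0)
        np.testing.assert_allclose(smoothed.derivative(t), 2.0, atol=1e-6)

    def test_noise_suppression(self):
        """Default smoothing keeps spurious derivatives of constant-plus-
        noise data below 3 sigma_n per hour."""
        rng = np.random.default_rng(42)
        sigma_n = 1.5
        t = np.linspace(0, 20, 40)
        f = 30.0 + rng.normal(0, sigma_n, 40)
        smoothed = smooth_trace(_trace(t, f))
        assert np.max(np.abs(smoothed.derivative(t))) <= 3 * sigma_n

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="4"):
            smooth_trace(_trace([0, 1, 2], [1, 2, 3]))

    def test_no_extrapolation(self):
        t = np.linspace(0, 10, 10)
        smoothed = smooth_trace(_trace(t, t**2), smoothing_factor=0.0)
        with pytest.raises(ValueError, match="outside"):
            smoothed(11.0)
        with pytest.raises(ValueError, match="outside"):
            smoothed.derivative(-0.5)


class TestExpressionRate:
    def test_constant_F_pure_dilution(self):
        """With F constant the derivative term vanishes: KF = mu(t) c."""
        c = 40.0
        t = np.linspace(0, 20, 30)
        fit = _flat_fit(mu_max=0.8, t0=10.0)
        smoothed = smooth_trace(_trace(t, np.full(30, c)), smoothing_factor=0.0)
        curve = expression_rate(smoothed, fit, t)
        mu = fit.mu_max / (np.exp(fit.mu_max * (t - fit.t0)) + 1.0)
        np.testing.assert_allclose(curve.KF, mu * c, rtol=1e-9)

    def test_dilution_free_limit(self):
        """With negligible mu, KF reduces to the slope of F."""
        k = 3.5
        t = np.linspace(0, 20, 30)
        fit = _flat_fit(mu_max=1e-12, t0=10.0)
        smoothed = smooth_trace(_trace(t, k * t), smoothing_factor=0.0)
        curve = expression_rate(smoothed, fit, t[1:-1])
        np.testing.assert_allclose(curve.KF, k, rtol=1e-6)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 20, 40)
        f = 20 + 5 * np.sin(t / 3) + rng.normal(0, 0.5, 40)
        fit = _flat_fit(mu_max=0.5, t0=10.0)
        s1 = smooth_trace(_trace(t, f), smoothing_factor=1.0)
        s2 = smooth_trace(_trace(t, 2 * f), smoothing_factor=4.0)  # s scales as c^2
        k1 = expression_rate(s1, fit, t).KF
        k2 = expression_rate(s2, fit, t).KF
        np.testing.assert_allclose(k2, 2 * k1, rtol=1e-6)

    def test_unit_rescaling_with_minutes(self):
        """Expressing times in minutes divides both dF/dt and mu by 60,
        hence KF by 60: the rate carries inverse time units."""
        t_h = np.linspace(1, 20, 30)
        f = 10 + 2 * t_h
        fit_h = _flat_fit(mu_max=0.5, t0=10.0)
        fit_min = GrowthModelFit(
            colony_id=0, Amax=fit_h.Amax, mu_max=fit_h.mu_max / 60.0,
            t0=fit_h.t0 * 60.0, residual_rms=0.0, n_points_used=10,
        )
        s_h = smooth_trace(_trace(t_h, f), smoothing_factor=0.0)
        s_min = smooth_trace(_trace(t_h * 60.0, f), smoothing_factor=0.0)
        k_h = expression_rate(s_h, fit_h, t_h).KF
        k_min = expression_rate(s_min, fit_min, t_h * 60.0).KF
        np.testing.assert_allclose(k_min, k_h / 60.0, rtol=1e-6)

    def test_steady_state_identity(self):
        """At fluorescence steady state with constant mu, F = KF / mu and
        the estimator returns KF = mu F."""
        mu, kf = 0.4, 20.0
        t = np.linspace(0, 30, 50)
        f_ss = kf / mu
        # constant mu: a logistic far from its midpoint, mu(t) ~ mu_max
        fit = _flat_fit(mu_max=mu, t0=1e4)
        smoothed = smooth_trace(_trace(t, np.full(50, f_ss)), smoothing_factor=0.0)
        curve = expression_rate(smoothed, fit, t)
        np.testing.assert_allclose(curve.KF, kf, rtol=1e-6)
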