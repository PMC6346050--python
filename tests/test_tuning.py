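"""Tuning curves, Gaussian fits, alignment, and gain decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from striatune import synth
from striatune.responses import ResponseWindow
from striatune.tuning import (
    ConditionTransform,
    GaussianFit,
    InsufficientCoverageError,
    NotResponsiveError,
    TuningCurve,
    align_and_normalize,
    apply_transform,
    best_frequency,
    build_tuning_curve,
    decompose_gain,
    fit_gaussian,
    fit_transform_lsq,
    peak_rates,
    select_analysis_intensity,
    shoulder_rates,
    smooth_curve,
    tuning_width,
)

FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # Gaussian full width at half max / sigma


class TestSelectAnalysisIntensity:
    def test_lower_responsive_intensity_wins(self):
        assert select_analysis_intensity({50: True, 60: True, 70: True}) == 60
        assert select_analysis_intensity({60: False, 70: True}) == 70

    def test_50db_alone_does_not_qualify(self):
        with pytest.raises(NotResponsiveError):
            select_analysis_intensity({50: True, 60: False, 70: False})


class TestBestFrequency:
    def test_argmax(self, gaussian_curve):
        assert best_frequency(gaussian_curve(f0_khz=8.0)) == pytest.approx(8.0)

    def test_tie_breaks_to_lowest_frequency(self):
        curve = TuningCurve(np.array([4.0, 8.0, 16.0]), np.array([1.0, 5.0, 5.0]))
        assert best_frequency(curve) == 8.0

    def test_matches_brute_force_argmax(self, freq_grid, rng):
        rates = rng.normal(0, 5, freq_grid.size)
        curve = TuningCurve(freq_grid, rates)
        brute = min(
            (f for f, r in zip(freq_grid, rates) if r == rates.max()),
        )
        assert best_frequency(curve) == pytest.approx(brute)

    @given(scale=hst.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_positive_rescaling(self, scale):
        freqs = 2.0 * 2.0 ** (0.25 * np.arange(19))
        rates = np.sin(np.arange(19)) + 2.0
        curve = TuningCurve(freqs, rates)
        assert best_frequency(TuningCurve(freqs, scale * rates)) == best_frequency(curve)


class TestSmoothCurve:
    def test_constant_curve_unchanged(self, freq_grid):
        curve = TuningCurve(freq_grid, np.full(freq_grid.size, 3.0))
        assert np.allclose(smooth_curve(curve).smoothed_rates_hz, 3.0)

    def test_quadratic_reproduced_exactly_by_order2_filter(self, freq_grid):
        y = 0.5 * np.arange(freq_grid.size) ** 2 - np.arange(freq_grid.size)
        out = smooth_curve(TuningCurve(freq_grid, y)).smoothed_rates_hz
        assert np.allclose(out, y, atol=1e-9)

    def test_impulse_gives_known_savitzky_golay_kernel(self, freq_grid):
        y = np.zeros(freq_grid.size)
        y[9] = 1.0
        out = smooth_curve(TuningCurve(freq_grid, y)).smoothed_rates_hz
        kernel = np.array([-3.0, 12.0, 17.0, 12.0, -3.0]) / 35.0
        assert np.allclose(out[7:12], kernel, atol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientCoverageError):
            smooth_curve(TuningCurve(np.array([1.0, 2.0, 4.0]), np.zeros(3)))


class TestTuningWidth:
    def test_triangular_profile_geometry(self):
        # peak 10 at 16 kHz falling linearly in log2(f) to 0 at +/- 1 octave
        x = np.linspace(np.log2(16) - 1.5, np.log2(16) + 1.5, 61)
        rates = np.clip(10.0 * (1.0 - np.abs(x - np.log2(16))), 0.0, None)
        tw = tuning_width(TuningCurve(2.0**x, rates))
        assert tw.width_oct == pytest.approx(1.0, abs=0.01)
        assert not tw.truncated

    def test_rectangular_plateau(self):
        x = np.arange(0, 4.01, 0.125)
        rates = np.where((x >= 1.5) & (x <= 2.5), 10.0, 0.0)
        tw = tuning_width(TuningCurve(2.0**x, rates))
        assert tw.width_oct == pytest.approx(1.0, abs=0.13)  # one grid step of slack

    def test_gaussian_fwhm_closed_form(self):
        x = np.linspace(1.0, 5.5, 200)
        rates = 10.0 * np.exp(-0.5 * (x - 4.0) ** 2 / 0.5**2)
        tw = tuning_width(TuningCurve(2.0**x, rates))
        assert tw.width_oct == pytest.approx(0.5 * FWHM, rel=0.02)

    def test_truncation_flagged_at_grid_edge(self, gaussian_curve):
        curve = gaussian_curve(A=10.0, f0_khz=2.5, sigma=2.0, B=0.0)
        assert tuning_width(curve).truncated

    def test_invariant_under_rescaling_and_refinement(self):
        x_coarse = np.linspace(2.0, 6.0, 17)
        x_fine = np.linspace(2.0, 6.0, 161)
        shape = lambda x: 8.0 * np.exp(-0.5 * (x - 4.0) ** 2 / 0.36)
        w_coarse = tuning_width(TuningCurve(2.0**x_coarse, shape(x_coarse)))
        w_scaled = tuning_width(TuningCurve(2.0**x_coarse, 7.3 * shape(x_coarse)))
        w_fine = tuning_width(TuningCurve(2.0**x_fine, shape(x_fine)))
        assert w_scaled.width_oct == pytest.approx(w_coarse.width_oct, rel=1e-9)
        assert w_fine.width_oct == pytest.approx(w_coarse.width_oct, rel=0.02)

    def test_uses_smoothed_rates_when_present(self, freq_grid, rng):
        rates = 10.0 * np.exp(
            -0.5 * (np.log2(freq_grid) - np.log2(11.3)) ** 2 / 0.25
        ) + rng.normal(0, 0.5, freq_grid.size)
        smoothed = smooth_curve(TuningCurve(freq_grid, rates))
        w_raw = tuning_width(TuningCurve(freq_grid, rates))
        w_smooth = tuning_width(smoothed)
        assert w_smooth.width_oct != w_raw.width_oct  # smoothing changed the read


class TestFitGaussian:
    def test_noiseless_recovery_to_four_significant_figures(self, gaussian_curve):
        fit = fit_gaussian(gaussian_curve(A=10.0, f0_khz=16.0, sigma=0.5, B=2.0))
        assert fit.A == pytest.approx(10.0, rel=1e-4)
        assert fit.f0 == pytest.approx(np.log2(16.0), abs=1e-4)
        assert fit.sigma == pytest.approx(0.5, rel=1e-4)
        assert fit.B == pytest.approx(2.0, rel=1e-4)
        assert fit.r_squared > 0.999
        assert fit.included

    def test_flat_noisy_curve_excluded(self, freq_grid, rng):
        fit = fit_gaussian(TuningCurve(freq_grid, rng.normal(0, 1, freq_grid.size)))
        assert fit.r_squared <= 0.4 or not fit.included
        assert not fit.included

    def test_recovery_error_shrinks_with_trials_per_frequency(self, freq_grid):
        """Median parameter error improves monotonically over 5/20/80 trials."""
        x = np.log2(freq_grid)
        med_err = []
        for n_trials in (5, 20, 80):
            errs = []
            for u in range(30):
                rng = np.random.default_rng(100 * n_trials + u)
                A, sig = rng.uniform(15, 35), rng.uniform(0.4, 0.8)
                f0 = rng.uniform(x[4], x[-5])
                true = A * np.exp(-0.5 * (x - f0) ** 2 / sig**2)
                curve = synth.noisy_tuning_curve(freq_grid, true, n_trials, rng)
                fit = fit_gaussian(curve)
                errs.append(abs(fit.A - A) / A + abs(fit.sigma - sig) / sig)
            med_err.append(np.median(errs))
        assert med_err[0] > med_err[1] > med_err[2]


class TestBuildTuningCurve:
    def test_recovers_generating_profile(self, rng):
        spec = synth.UnitSpec(
            unit_id=0,
            baseline_rate_hz=5.0,
            tuning_A_hz=30.0,
            tuning_sigma_oct=0.6,
            kernel=synth.ResponseKernel("onset", 0.015, 0.025),
        )
        freqs = np.asarray(synth.DEFAULT_FREQ_GRID_KHZ)
        reps = 25
        trials = pd.DataFrame(
            {
                "onset_s": 1.0 + 2.0 * np.arange(freqs.size * reps),
                "freq_khz": np.tile(freqs, reps),
                "intensity_db": 60.0,
                "duration_s": 0.1,
                "light_on": False,
            }
        )
        spikes = synth.simulate_unit_trials(spec, trials, seed=21)
        window = ResponseWindow(0.015, 0.040, "excite")
        curve = build_tuning_curve(spikes, trials, window, spec.baseline_rate_hz)
        true = synth.modulated_evoked(spec, freqs, light_on=False)
        se = np.sqrt((spec.baseline_rate_hz + true) / (reps * 0.025))
        assert np.all(np.abs(curve.rates_hz - true) < 4 * se + 1.0)

    def test_untuned_unit_gives_flat_curve_near_zero(self, rng):
        spec = synth.UnitSpec(
            unit_id=0, baseline_rate_hz=8.0, tuning_A_hz=0.0, tuning_B_hz=0.0
        )
        freqs = np.asarray(synth.DEFAULT_FREQ_GRID_KHZ)
        reps = 30
        trials = pd.DataFrame(
            {
                "onset_s": 1.0 + 2.0 * np.arange(freqs.size * reps),
                "freq_khz": np.tile(freqs, reps),
                "intensity_db": 60.0,
                "duration_s": 0.1,
                "light_on": False,
            }
        )
        spikes = synth.simulate_unit_trials(spec, trials, seed=22)
        curve = build_tuning_curve(
            spikes, trials, ResponseWindow(0.01, 0.05, "excite"), 8.0
        )
        se = np.sqrt(8.0 / (reps * 0.04))  # Poisson SE of one curve point
        assert np.all(np.abs(curve.rates_hz) < 4 * se)
        assert abs(curve.rates_hz.mean()) < se

    def test_insufficient_frequency_coverage_rejected(self):
        trials = pd.DataFrame(
            {"onset_s": [1.0, 2.0], "freq_khz": [4.0, 8.0]}
        )
        with pytest.raises(InsufficientCoverageError):
            build_tuning_curve([], trials, ResponseWindow(0.01, 0.05, "excite"), 0.0)


class TestDecomposeGain:
    def test_hand_checked_algebra(self):
        ctrl = GaussianFit(1.0, 3.0, 0.5, 0.1, 0.9, True)
        light = GaussianFit(0.5, 3.0, 0.5, 0.05, 0.9, True)
        tr = decompose_gain(ctrl, light)
        assert tr.scale == pytest.approx(2.0)
        assert tr.offset == pytest.approx(0.0)

    def test_identical_fits_give_identity_transform(self):
        fit = GaussianFit(8.0, 3.5, 0.6, 1.0, 0.95, True)
        tr = decompose_gain(fit, fit)
        assert tr.scale == pytest.approx(1.0)
        assert tr.offset == pytest.approx(0.0)

    @given(
        offset=hst.floats(-0.5, 0.5),
        scale=hst.floats(1.05, 4.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_apply_then_decompose_is_identity(self, offset, scale):
        ctrl = GaussianFit(10.0, 3.0, 0.5, 1.0, 0.99, True)
        light = apply_transform(ctrl, ConditionTransform(offset, scale))
        tr = decompose_gain(ctrl, light)
        assert tr.scale == pytest.approx(scale, rel=1e-9)
        assert tr.offset == pytest.approx(offset, abs=1e-9)

    def test_lsq_fallback_matches_on_exact_transform(self, gaussian_curve):
        ctrl = gaussian_curve(A=10.0, f0_khz=16.0, sigma=0.5, B=1.0)
        light = TuningCurve(ctrl.freqs_khz, (ctrl.rates_hz - 0.4) / 1.8)
        tr = fit_transform_lsq(ctrl, light)
        assert tr.scale == pytest.approx(1.8, rel=1e-9)
        assert tr.offset == pytest.approx(0.4, abs=1e-9)

    def test_population_recovery_of_generating_transform(self, freq_grid):
        """Divisive generator's (1.8, 0.01) recovered as the population mean."""
        x = np.log2(freq_grid)
        scales, offsets = [], []
        rng = np.random.default_rng(404)
        for u in range(25):
            A, B = rng.uniform(15, 40), rng.uniform(0, 2)
            f0, sig = rng.uniform(x[4], x[-5]), rng.uniform(0.35, 0.9)
            ctrl_true = A * np.exp(-0.5 * (x - f0) ** 2 / sig**2) + B
            light_true = (ctrl_true - 0.01 * (A + B)) / 1.8
            fc = fit_gaussian(synth.noisy_tuning_curve(freq_grid, ctrl_true, 20, rng))
            fl = fit_gaussian(synth.noisy_tuning_curve(freq_grid, light_true, 20, rng))
            if fc.included and fl.included and fl.A > 0:
                tr = decompose_gain(fc, fl, normalize=True)
                scales.append(tr.scale)
                offsets.append(tr.offset)
        assert len(scales) >= 15
        assert np.mean(scales) == pytest.approx(1.8, rel=0.05)
        assert abs(np.mean(offsets) - 0.01) < 0.05


class TestAlignAndNormalize:
    def test_identical_conditions_peak_at_one(self, gaussian_curve):
        curve = gaussian_curve(A=10.0, f0_khz=16.0, sigma=0.5)
        pop = align_and_normalize([(curve, curve)])
        at_zero = np.isclose(pop.octave_offsets, 0.0)
        assert pop.mean_norm_rates["control"][at_zero] == pytest.approx(1.0)
        assert pop.mean_norm_rates["light"][at_zero] == pytest.approx(1.0)

    def test_halved_light_condition_scales_population_curve(self, gaussian_curve):
        curves = []
        for f0 in (8.0, 11.3, 16.0):
            ctrl = gaussian_curve(A=10.0, f0_khz=f0, sigma=0.5, B=0.0)
            light = TuningCurve(ctrl.freqs_khz, ctrl.rates_hz / 2.0)
            curves.append((ctrl, light))
        pop = align_and_normalize(curves)
        finite = np.isfinite(pop.mean_norm_rates["control"])
        assert np.allclose(
            pop.mean_norm_rates["light"][finite],
            0.5 * pop.mean_norm_rates["control"][finite],
        )

    def test_nonpositive_control_peak_excluded(self, freq_grid, gaussian_curve):
        good = gaussian_curve()
        bad = TuningCurve(freq_grid, np.full(freq_grid.size, -1.0))
        pop = align_and_normalize([(good, good), (bad, bad)])
        assert pop.n_units == 1


class TestShoulderAndPeak:
    def _population(self, gaussian_curve, light_fn, n=12):
        curves = []
        for i in range(n):
            f0 = [8.0, 11.3, 16.0, 22.6][i % 4]
            ctrl = gaussian_curve(A=10.0 + i, f0_khz=f0, sigma=0.5, B=0.5)
            curves.append((ctrl, light_fn(ctrl)))
        return align_and_normalize(curves)

    def test_uniform_divisive_gain_halves_shoulders(self, gaussian_curve):
        pop = self._population(
            gaussian_curve,
            lambda c: TuningCurve(c.freqs_khz, c.rates_hz / 2.0),
        )
        sh = shoulder_rates(pop)
        assert np.allclose(sh.light, sh.control / 2.0)
        assert sh.p_value < 0.01

    def test_identical_conditions_give_zero_difference(self, gaussian_curve):
        pop = self._population(gaussian_curve, lambda c: c)
        sh = shoulder_rates(pop)
        assert sh.mean_difference == pytest.approx(0.0)
        assert sh.p_value == 1.0

    def test_peak_only_suppression_spares_shoulders(self, freq_grid, gaussian_curve):
        """Cortical-silencing model: loss is preferential to the peak.

        The suppressed bump (15% deep, FWHM 1/2 octave) barely touches the
        true rate half an octave out; both conditions carry realistic
        measurement noise. The signature separating this from a divisive
        gain: the peak drops significantly while the shoulder ratio stays
        near 1 (a 1.8x divisive gain would push it to ~0.55), and the peak
        loss dominates the (realignment-induced) shoulder change.
        """
        rng = np.random.default_rng(77)
        x = np.log2(freq_grid)
        sigma_n = 0.5 / FWHM

        def pair_fn(ctrl):
            f0 = np.log2(best_frequency(ctrl))
            bump = np.exp(-0.5 * (x - f0) ** 2 / sigma_n**2)
            noise_sd = 0.08 * ctrl.rates_hz.max()
            noisy_ctrl = TuningCurve(
                freq_grid, ctrl.rates_hz + rng.normal(0, noise_sd, x.size)
            )
            light = TuningCurve(
                freq_grid,
                ctrl.rates_hz * (1.0 - 0.15 * bump)
                + rng.normal(0, noise_sd, x.size),
            )
            return noisy_ctrl, light

        curves = []
        for i in range(20):
            ctrl = gaussian_curve(
                A=10.0 + i, f0_khz=[8.0, 11.3, 16.0, 22.6][i % 4], sigma=0.5, B=0.5
            )
            curves.append(pair_fn(ctrl))
        pop = align_and_normalize(curves)
        pk, sh = peak_rates(pop), shoulder_rates(pop)
        peak_drop = 1.0 - pk.light.mean() / pk.control.mean()
        assert pk.p_value < 0.01 and peak_drop > 0.05
        # far from the ~0.55 a 1.8x divisive gain would produce
        assert sh.light.mean() / sh.control.mean() > 0.85
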