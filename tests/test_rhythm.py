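"""Autocorrelation, interval ANOVA, cosinor fitting and the LS spectrum."""

import math

import numpy as np
import pytest

from chronuria import (
    ChronuriaError,
    DegenerateDesignError,
    SeriesValidationError,
    acf,
    cosinor_fit,
    correct_volume,
    interval_anova,
    ls_spectrum,
    pooling_attenuation,
    subset_by_phase,
    uncorrected,
)

from conftest import build_corrected
from oracles import acf_oracle, anova_oracle, grid_cosinor_oracle


def cosine_series(mesor, amplitude, period, peak_time, times, offset=0.0):
    omega = 2.0 * math.pi / period
    values = mesor + amplitude * np.cos(omega * (times - peak_time))
    return build_corrected(values, times=times + offset)


class TestAcf:
    def test_lag_zero_is_one(self, rng):
        s = build_corrected(rng.uniform(1, 10, 20))
        res = acf(s, max_lag=5)
        assert res.coefficients[0] == 1.0
        assert np.all(np.abs(res.coefficients) <= 1.0 + 1e-12)

    def test_alternating_series_lag1(self):
        # x = +1,-1,... (length 8) around mean 0: r_1 = -7/8
        s = build_corrected(5.0 + np.array([1.0, -1.0] * 4))
        res = acf(s, max_lag=2)
        assert res.coefficients[1] == pytest.approx(-0.875)

    def test_confidence_limit_convention(self):
        s = build_corrected(np.arange(1.0, 26.0))
        res = acf(s, max_lag=3)
        assert res.conf_limit == pytest.approx(1.959964 / math.sqrt(25),
                                               abs=1e-5)

    def test_matches_direct_summation(self, rng):
        values = rng.uniform(1, 50, 30)
        res = acf(build_corrected(values), max_lag=6)
        for k in range(7):
            assert res.coefficients[k] == \
                pytest.approx(acf_oracle(values, k), abs=1e-10)

    def test_white_noise_band_coverage(self):
        # ~5% of lag-1 coefficients should fall outside +/-1.96/sqrt(n)
        hits = 0
        n_sim = 500
        for seed in range(n_sim):
            r = np.random.default_rng(seed)
            s = build_corrected(100.0 + r.standard_normal(63))
            res = acf(s, max_lag=1)
            hits += abs(res.coefficients[1]) >= res.conf_limit
        assert 0.02 <= hits / n_sim <= 0.09

    def test_constant_series_rejected(self):
        with pytest.raises(ChronuriaError):
            acf(build_corrected(np.full(20, 3.0)), max_lag=3)

    def test_phase_subset_rejected(self):
        s = build_corrected([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        night_only = subset_by_phase(s, "night")
        with pytest.raises(SeriesValidationError, match="gap-free"):
            acf(night_only, max_lag=1)


class TestIntervalAnova:
    def test_hand_computed_example(self):
        # groups {1,2} and {3,4}: SSB = 4, SSW = 1 -> F = 8 on (1, 2) df
        s = build_corrected([1.0, 2.0, 3.0, 4.0])
        res = interval_anova(s, group_len=2)
        assert res.F == pytest.approx(8.0)
        assert (res.df_between, res.df_within) == (1, 2)

    def test_equal_group_means_give_zero_f(self):
        s = build_corrected([1.0, 3.0, 3.0, 1.0, 2.0, 2.0])
        res = interval_anova(s, group_len=2)
        assert res.F == pytest.approx(0.0)

    def test_single_group_rejected(self):
        with pytest.raises(SeriesValidationError):
            interval_anova(build_corrected([1.0, 2.0, 3.0]), group_len=8)

    def test_partial_tail_modes(self, rng):
        values = rng.uniform(1, 10, 19)
        s = build_corrected(values)
        inc = interval_anova(s, group_len=8, partial_tail="include")
        drop = interval_anova(s, group_len=8, partial_tail="drop")
        assert inc.df_between == 2 and drop.df_between == 1
        assert inc.group_sizes.tolist() == [8, 8, 3]

    def test_matches_direct_formula(self, rng):
        values = rng.uniform(1, 10, 24)
        res = interval_anova(build_corrected(values), group_len=8)
        f_exp, dfb, dfw = anova_oracle([values[0:8], values[8:16],
                                        values[16:24]])
        assert res.F == pytest.approx(f_exp, abs=1e-10)
        assert (res.df_between, res.df_within) == (dfb, dfw)


class TestCosinor:
    def test_noiseless_exact_recovery(self):
        times = np.arange(24.0)
        s = cosine_series(5.0, 2.0, 24.0, 0.0, times)
        fit = cosinor_fit(s, 24.0)
        assert fit.mesor == pytest.approx(5.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-9)
        assert fit.acrophase == pytest.approx(0.0, abs=1e-9)
        assert fit.percent_rhythm == pytest.approx(1.0, abs=1e-12)
        assert fit.p_zero_amplitude == 0.0

    def test_quarter_period_peak_gives_minus_90_degrees(self):
        # peak at tau/4 = 22.5 h of a 90-h cosine on the 12-h midpoint grid
        times = 6.0 + 12.0 * np.arange(16)
        s = cosine_series(3.0, 1.0, 90.0, 22.5, times)
        fit = cosinor_fit(s, 90.0)
        assert fit.acrophase == pytest.approx(-90.0, abs=1e-9)
        assert fit.peak_time == pytest.approx(22.5, abs=1e-9)

    def test_peak_value_self_consistency(self, rng):
        for _ in range(25):
            values = rng.uniform(1, 10, 21)
            s = build_corrected(values)
            fit = cosinor_fit(s, 90.0)
            peak_val = fit.predict(fit.peak_time)
            grid = fit.predict(fit.peak_time
                               + np.linspace(0, 90.0, 3600, endpoint=False))
            assert peak_val == pytest.approx(fit.mesor + fit.amplitude,
                                             abs=1e-9)
            assert peak_val >= np.max(grid) - 1e-9

    def test_acrophase_shift_covariance(self):
        # shifting the time origin by delta changes phi by +360*delta/tau
        times = 6.0 + 12.0 * np.arange(20)
        tau = 90.0
        base = cosinor_fit(cosine_series(3.0, 1.0, tau, 40.0, times), tau)
        for delta in (6.0, 17.0, 100.0):
            shifted = cosinor_fit(
                cosine_series(3.0, 1.0, tau, 40.0 - delta, times), tau)
            expected = (base.acrophase + 360.0 * delta / tau) % 360.0
            got = shifted.acrophase % 360.0
            assert got == pytest.approx(expected, abs=1e-8)

    def test_degenerate_period_rejected(self):
        s = build_corrected(np.arange(1.0, 17.0))
        with pytest.raises(DegenerateDesignError):
            cosinor_fit(s, 12.0)  # trial period equal to the grid step

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 18))
            times = 6.0 + 12.0 * np.arange(n)
            values = rng.uniform(1, 10, n)
            s = build_corrected(values, times=times)
            tau = float(rng.uniform(60, 200))
            fit = cosinor_fit(s, tau)
            m, a, phi = grid_cosinor_oracle(times, values, tau)
            assert fit.amplitude == pytest.approx(a, abs=5e-3)
            if fit.amplitude > 0.05:
                d = (fit.acrophase - phi) % 360.0
                assert min(d, 360.0 - d) <= 1.0
            assert fit.mesor == pytest.approx(m, abs=5e-3)


class TestSpectrum:
    def test_pure_90h_cosine_peaks_at_k8(self):
        times = 6.0 + 12.0 * np.arange(60)  # spans one 720-h fundamental
        s = cosine_series(10.0, 2.0, 90.0, 10.0, times)
        sp = ls_spectrum(s, fundamental=720.0)
        band = sp.peak_band
        assert band.best_harmonic == 8
        assert band.best_period == pytest.approx(90.0)
        assert sp.fit_at(90.0).percent_rhythm == pytest.approx(1.0, abs=1e-6)
        others = [f.percent_rhythm for f in sp.fits
                  if f.trial_period != 90.0]
        assert max(others) < 0.05

    def test_trial_periods_are_harmonics_of_fundamental(self, subject1):
        sp = ls_spectrum(uncorrected(subject1), fundamental=720.0)
        for k, fit in zip(sp.harmonics, sp.fits):
            assert fit.trial_period == pytest.approx(720.0 / k)
        assert np.all(np.diff(sp.periods) < 0)
        # Nyquist: no trial period below twice the 12-h sampling step
        assert sp.periods.min() >= 24.0

    def test_percent_rhythm_parseval_bound(self, rng):
        # orthogonal harmonic basis on a complete span: sum of PR <= 1
        times = 6.0 + 12.0 * np.arange(60)
        values = 50.0 + rng.standard_normal(60)
        sp = ls_spectrum(build_corrected(values, times=times),
                         fundamental=720.0)
        assert sp.percent_rhythm.sum() <= 1.0 + 1e-9

    def test_day_subset_recovers_same_peak(self):
        times = 6.0 + 12.0 * np.arange(60)
        s = cosine_series(10.0, 2.0, 90.0, 10.0, times)
        day = subset_by_phase(s, "day")
        assert not day.is_equidistant or day.n == 30
        sp = ls_spectrum(day, fundamental=720.0)
        assert sp.peak_band.best_period == pytest.approx(90.0)

    def test_subset_counts_and_time_axis(self, subject1):
        s = correct_volume(subject1)
        day = subset_by_phase(s, "day")
        night = subset_by_phase(s, "night")
        assert day.n == 32 and night.n == 31  # 63 intervals starting day
        assert set(day.phases) == {"day"}
        np.testing.assert_array_equal(day.times, s.times[s.phases == "day"])


def test_pooling_attenuation_values():
    assert pooling_attenuation(90.0, 0.0) == 1.0
    x = math.pi * 12.0 / 90.0
    assert pooling_attenuation(90.0, 12.0) == pytest.approx(math.sin(x) / x)
    # 24-h rhythm pooled over 12-h windows: sin(pi/2)/(pi/2) = 2/pi
    assert pooling_attenuation(24.0, 12.0) == pytest.approx(2.0 / math.pi)
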