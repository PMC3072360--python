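"""Measure battery: moments, spectra, spectral slope, slowest mode, Wolf
Lyapunov exponent, and the failure-capturing aggregate."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmnshape import (MeasureBattery, lyapunov_wolf, measure_battery, moments,
                      power_spectrum, slowest_mode_period, spectral_alpha)
from pmnshape.exceptions import (DegenerateSeriesError, InsufficientBinsError,
                                 NoQualifyingPeakError, SeriesTooShortError)
from pmnshape.measures import MEASURE_ORDER, delay_embed_values


def brute_force_moments(x):
    n = len(x)
    s1 = sum(x) / n
    var = sum((v - s1) ** 2 for v in x) / n
    m3 = sum((v - s1) ** 3 for v in x) / n
    m4 = sum((v - s1) ** 4 for v in x) / n
    sd = math.sqrt(sum((v - s1) ** 2 for v in x) / (n - 1))
    return s1, sd, m3 / var ** 1.5, m4 / var ** 2 - 3.0


class TestMoments:
    def test_matches_brute_force(self, rng):
        x = rng.normal(1.5, 0.1, size=500)
        mom = moments(x)
        s1, sd, s3, s4 = brute_force_moments(x.tolist())
        assert mom.s1 == pytest.approx(s1, abs=1e-12)
        assert mom.s2 == pytest.approx(sd, abs=1e-12)
        assert mom.s3 == pytest.approx(s3, abs=1e-12)
        assert mom.s4 == pytest.approx(s4, abs=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0.5, max_value=5.0,
                              allow_nan=False), min_size=4, max_size=64))
    def test_property_matches_brute_force(self, xs):
        x = np.asarray(xs)
        if np.ptp(x) == 0:
            with pytest.raises(DegenerateSeriesError):
                moments(x)
            return
        mom = moments(x)
        s1, sd, s3, s4 = brute_force_moments(xs)
        assert mom.s1 == pytest.approx(s1, rel=1e-9)
        assert mom.s3 == pytest.approx(s3, rel=1e-6, abs=1e-9)
        assert mom.s4 == pytest.approx(s4, rel=1e-6, abs=1e-9)

    def test_known_skewed_sample(self):
        # exponential-ish: positive skewness
        x = np.array([0.1, 0.1, 0.2, 0.2, 0.3, 0.5, 0.9, 2.5])
        assert moments(x).s3 > 0

    def test_degenerate_constant(self):
        with pytest.raises(DegenerateSeriesError) as exc:
            moments(np.full(10, 2.0))
        assert exc.value.s1 == 2.0

    def test_too_short(self):
        with pytest.raises(SeriesTooShortError):
            moments([1.0, 2.0, 3.0])


class TestPowerSpectrum:
    def test_parseval(self, rng):
        for n in (128, 129):
            x = rng.normal(size=n)
            spec = power_spectrum(x, dt=2.0)
            assert spec.power.sum() == pytest.approx(x.var(), rel=1e-10)

    def test_pure_sine_single_bin(self):
        n, k = 256, 12
        t = np.arange(n)
        x = 1.0 + 0.3 * np.sin(2 * math.pi * k * t / n)
        spec = power_spectrum(x, dt=2.0)
        assert int(np.argmax(spec.power)) == k - 1  # power[0] is bin 1
        assert spec.power[k - 1] == pytest.approx(0.3 ** 2 / 2, rel=1e-9)

    def test_frequencies(self):
        spec = power_spectrum(np.random.default_rng(0).normal(size=100),
                              dt=2.0)
        assert spec.frequencies[0] == pytest.approx(1.0 / 200.0)
        assert spec.frequencies.size == 50

    def test_too_short(self):
        with pytest.raises(SeriesTooShortError):
            power_spectrum(np.ones(8))


class TestSpectralAlpha:
    def test_exact_powerlaw_recovered(self):
        # synthesize a spectrum directly with power ~ f^-1.5
        spec = power_spectrum(np.random.default_rng(5).normal(size=600))
        f = spec.frequencies
        spec.power = f ** -1.5
        assert spectral_alpha(spec) == pytest.approx(-1.5, abs=1e-9)

    def test_default_band_is_middle_third_of_log_axis(self):
        spec = power_spectrum(np.random.default_rng(6).normal(size=600))
        f = spec.frequencies
        lf = np.log10(f)
        lims = lf[0] + (lf[-1] - lf[0]) * np.array([1 / 3, 2 / 3])
        lo, hi = np.searchsorted(lf, lims)
        # slope -2 inside the fit band, flat outside: only the band matters
        spec.power = np.ones(f.size)
        spec.power[lo:hi] = (f[lo:hi] / f[lo]) ** -2 * 5.0
        assert spectral_alpha(spec) == pytest.approx(-2.0, abs=1e-9)

    def test_index_band_variant(self):
        spec = power_spectrum(np.random.default_rng(6).normal(size=600))
        f = spec.frequencies
        m = f.size
        lo, hi = math.ceil(m / 3), math.ceil(2 * m / 3)
        spec.power = np.ones(m)
        spec.power[lo:hi] = (f[lo:hi] / f[lo]) ** -2 * 5.0
        assert spectral_alpha(spec, band="middle_third_index") \
            == pytest.approx(-2.0, abs=1e-9)
        with pytest.raises(ValueError):
            spectral_alpha(spec, band="upper_half")

    def test_insufficient_bins(self):
        spec = power_spectrum(np.random.default_rng(7).normal(size=40))
        spec.power = np.zeros_like(spec.power)
        with pytest.raises(InsufficientBinsError):
            spectral_alpha(spec)


class TestSlowestModePeriod:
    def test_pure_slow_sine(self):
        n, dt = 900, 2.0
        t = np.arange(n) * dt
        x = 1.0 + 0.1 * np.sin(2 * math.pi * t / 300.0)
        spec = power_spectrum(x, dt=dt)
        assert slowest_mode_period(spec) == pytest.approx(300.0 / 60.0,
                                                          rel=0.01)

    def test_slow_plus_fast_reports_slow(self):
        n, dt = 900, 2.0
        t = np.arange(n) * dt
        x = 1.0 + 0.1 * np.sin(2 * math.pi * t / 300.0) \
            + 0.12 * np.sin(2 * math.pi * t / 60.0)
        spec = power_spectrum(x, dt=dt)
        assert slowest_mode_period(spec) == pytest.approx(5.0, rel=0.01)

    def test_noise_bump_below_prominence_skipped(self):
        spec = power_spectrum(np.random.default_rng(8).normal(size=600),
                              dt=2.0)
        spec.power = np.full(spec.power.size, 0.01)
        spec.power[2] = 0.02    # small slow bump, below 25% of the max
        spec.power[40] = 1.0    # the real line
        spec.frequencies = spec.frequencies
        per = slowest_mode_period(spec)
        assert per == pytest.approx(1.0 / spec.frequencies[40] / 60.0)

    def test_argmax_mode(self):
        spec = power_spectrum(np.random.default_rng(9).normal(size=600),
                              dt=2.0)
        spec.power = np.full(spec.power.size, 1e-6)
        spec.power[10] = 1.0
        assert slowest_mode_period(spec, mode="argmax") == pytest.approx(
            1.0 / spec.frequencies[10] / 60.0)

    def test_no_qualifying_peak(self):
        spec = power_spectrum(np.random.default_rng(10).normal(size=600),
                              dt=2.0)
        spec.power = np.geomspace(1.0, 1e-4, spec.power.size)  # monotone
        with pytest.raises(NoQualifyingPeakError):
            slowest_mode_period(spec)


class TestLyapunovWolf:
    def test_logistic_map_oracle(self):
        # fully chaotic logistic map x -> 4x(1-x): Lambda1 = ln 2
        x = np.empty(3000)
        x[0] = 0.34
        for i in range(1, x.size):
            x[i] = 4.0 * x[i - 1] * (1.0 - x[i - 1])
        lam = lyapunov_wolf(x)
        assert lam == pytest.approx(math.log(2.0), abs=0.1)

    def test_periodic_signal_nonpositive(self):
        t = np.arange(2000)
        x = np.sin(2 * math.pi * t / 50.0)
        lam = lyapunov_wolf(x)
        assert lam < 0.05

    def test_too_short(self):
        with pytest.raises(SeriesTooShortError):
            lyapunov_wolf(np.random.default_rng(0).normal(size=100))

    def test_delay_embed_values(self):
        x = np.arange(10.0)
        pts = delay_embed_values(x, dim=3, delay=2)
        assert pts.shape == (6, 3)
        assert np.allclose(pts[0], [0.0, 2.0, 4.0])
        with pytest.raises(SeriesTooShortError):
            delay_embed_values(np.arange(4.0), dim=3, delay=2)


class TestMeasureBattery:
    def test_full_battery_on_ensemble(self, idle_measures):
        for ms in idle_measures:
            assert ms.failures == {}
            for name in MEASURE_ORDER:
                assert ms.get(name) is not None

    def test_captures_failures_instead_of_raising(self):
        ms = measure_battery(np.full(300, 1.5))
        assert ms.mean == 1.5
        assert "skew" in ms.failures
        assert "lambda1" in ms.failures or ms.lambda1 is not None

    def test_transformer_shape_and_nan(self, rng):
        X = [rng.normal(1.5, 0.1, size=400), np.full(400, 1.5)]
        out = MeasureBattery().fit(X).transform(X)
        assert out.shape == (2, 7)
        assert np.isnan(out[1, 2])   # constant row: skew missing
        names = MeasureBattery().get_feature_names_out()
        assert list(names) == list(MEASURE_ORDER) + ["slowest_period_min"]
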