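"""Pipeline tests: each stage against analytic/oracle expectations, then the chain."""

import numpy as np
import pytest

from bcghr import (
    AccelTrace,
    ConfigError,
    InputError,
    NoiseSpec,
    PipelineConfig,
    generate_beat_times,
    hr_series,
    make_hr_profile,
    synth_trace,
)
from bcghr.hrpipe import (
    MonoSignal,
    bandpass_bcg,
    combine_axes,
    detrend_ma,
    envelope_refine,
    estimate_hr_fft,
    fill_gaps,
    standardize_axes,
)

from conftest import TILTED
from test_synthgen import brute_dft_argmax

FS = 50.0


def tone(freq, duration=30.0, fs=FS, amp=1.0):
    t = np.arange(0, duration, 1 / fs)
    return MonoSignal(fs, amp * np.sin(2 * np.pi * freq * t))


class TestDetrend:
    def test_constant_maps_to_zero(self):
        sig = MonoSignal(FS, np.full(500, 3.7))
        out = detrend_ma(sig, 2.0)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_drift_suppressed(self):
        # 0.05 Hz sine: MA transfer leaves ~1 - sinc(0.1) ~ 1.6% residual
        out = detrend_ma(tone(0.05), 2.0)
        assert np.abs(out.values[100:-100]).max() <= 0.05

    def test_cardiac_band_retained(self):
        out = detrend_ma(tone(7.0), 2.0)
        assert np.abs(out.values[100:-100]).max() >= 0.95

    def test_near_idempotent_on_inband_content(self):
        # discrete MA gain at 7 Hz is ~1e-2, so D^2 vs D differs at that order
        once = detrend_ma(tone(7.0), 2.0)
        twice = detrend_ma(once, 2.0)
        rel = np.linalg.norm(twice.values - once.values) / np.linalg.norm(once.values)
        assert rel <= 0.05

    def test_window_longer_than_signal(self):
        with pytest.raises(ConfigError):
            detrend_ma(MonoSignal(FS, np.zeros(50)), 2.0)


class TestStandardizeCombine:
    def make_trace(self, seed=0):
        rng = np.random.default_rng(seed)
        return AccelTrace(FS, 0.0, rng.normal(2.0, 1.5, (400, 3)))

    def test_axes_zero_mean_unit_sd(self):
        std = standardize_axes(self.make_trace())
        assert np.allclose(std.samples.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(std.samples.std(axis=0), 1.0, atol=1e-12)

    def test_affine_invariance(self):
        tr = self.make_trace()
        scaled = AccelTrace(FS, 0.0, np.column_stack([
            3.2 * tr.samples[:, 0] + 7.0, tr.samples[:, 1], tr.samples[:, 2],
        ]))
        np.testing.assert_allclose(
            standardize_axes(tr).samples, standardize_axes(scaled).samples,
            atol=1e-9,
        )

    def test_constant_axis_becomes_zero(self):
        tr = self.make_trace()
        samples = tr.samples.copy()
        samples[:, 1] = 9.81
        std = standardize_axes(AccelTrace(FS, 0.0, samples))
        assert np.all(std.samples[:, 1] == 0.0)

    def test_combine_is_magnitude(self):
        s = np.sin(np.linspace(0, 10, 300))
        tr = AccelTrace(FS, 0.0, np.column_stack([s, np.zeros_like(s), np.zeros_like(s)]))
        np.testing.assert_allclose(combine_axes(tr).values, np.abs(s))

    def test_combine_permutation_and_sign_invariance(self):
        tr = self.make_trace()
        base = combine_axes(tr).values
        perm = AccelTrace(FS, 0.0, tr.samples[:, [2, 0, 1]])
        flip = AccelTrace(FS, 0.0, tr.samples * np.array([1.0, -1.0, 1.0]))
        np.testing.assert_array_equal(combine_axes(perm).values, base)
        np.testing.assert_array_equal(combine_axes(flip).values, base)


class TestBandpassEnvelope:
    def test_passband_tone_retained(self):
        out = bandpass_bcg(tone(7.0), (4.0, 11.0), 2)
        assert np.abs(out.values[200:-200]).max() >= 0.9

    def test_stopband_tone_rejected(self):
        out = bandpass_bcg(tone(0.2), (4.0, 11.0), 2)
        assert np.abs(out.values[200:-200]).max() <= 0.01

    def test_inverted_band_rejected(self):
        with pytest.raises(ConfigError):
            bandpass_bcg(tone(7.0), (11.0, 4.0), 2)

    def test_envelope_recovers_modulator(self):
        t = np.arange(0, 20, 1 / FS)
        am = MonoSignal(FS, (1 + 0.8 * np.sin(2 * np.pi * 1.2 * t)) * np.sin(2 * np.pi * 7 * t))
        env = envelope_refine(am, 3.0)
        f = brute_dft_argmax(env.values, FS, 0.3, 3.0, df=0.002)
        assert f == pytest.approx(1.2, abs=0.02)

    def test_zero_in_zero_out(self):
        env = envelope_refine(MonoSignal(FS, np.zeros(600)), 3.0)
        np.testing.assert_allclose(env.values, 0.0, atol=1e-15)

    def test_cutoff_beyond_nyquist(self):
        with pytest.raises(ConfigError):
            envelope_refine(tone(7.0), 30.0)


class TestEstimateHR:
    def test_pure_tone_estimate(self):
        est = estimate_hr_fft(tone(1.2, duration=20.0))
        assert est.bpm == pytest.approx(72.0, abs=0.5)
        assert est.confident

    def test_out_of_band_energy_ignored(self):
        t = np.arange(0, 20, 1 / FS)
        sig = MonoSignal(FS, 5 * np.sin(2 * np.pi * 3.5 * t) + 0.3 * np.sin(2 * np.pi * 1.0 * t))
        est = estimate_hr_fft(sig)
        assert est.bpm == pytest.approx(60.0, abs=0.5)

    def test_band_edge_maps_to_150(self):
        est = estimate_hr_fft(tone(2.5, duration=20.0))
        assert est.bpm == pytest.approx(150.0, abs=0.5)
        assert est.bpm <= 150.0

    def test_band_conversion_exact(self):
        lo, hi = PipelineConfig().search_band_hz
        assert 60.0 * hi == 150.0
        assert 60.0 * lo == pytest.approx(39.6)

    def test_short_signal_rejected(self):
        with pytest.raises(InputError):
            estimate_hr_fft(tone(1.2, duration=3.0))

    def test_oracle_equivalence_random_signals(self):
        """Selected pre-interpolation peak bin == brute-force in-band argmax."""
        rng = np.random.default_rng(2024)
        band = (0.66, 2.5)
        for _ in range(100):
            f0 = rng.uniform(0.7, 2.4)
            t = np.arange(0, 12, 1 / FS)
            v = np.sin(2 * np.pi * f0 * t) + 0.5 * rng.normal(size=t.size)
            sig = MonoSignal(FS, v)
            nfft = 4 * len(v)
            mag = np.abs(np.fft.rfft(v - v.mean(), nfft))
            freqs = np.fft.rfftfreq(nfft, 1 / FS)
            sel = np.nonzero((freqs >= band[0]) & (freqs <= band[1]))[0]
            oracle_bin_freq = freqs[sel[np.argmax(mag[sel])]]
            est = estimate_hr_fft(sig, band, 4)
            # interpolation moves the peak by at most half a bin
            half_bin = 0.5 * freqs[1]
            assert abs(est.bpm / 60.0 - oracle_bin_freq) <= half_bin + 1e-12


class TestHRSeries:
    def make_const_trace(self, bpm=72.0, duration=60.0, seed=0, orientation=(0, 0, 1.0)):
        prof = make_hr_profile([(duration, bpm, 0)])
        beats = generate_beat_times(prof, 0.02, seed=seed)
        return synth_trace(beats, noise=NoiseSpec(), orientation=orientation,
                           fs=FS, duration_s=duration, seed=seed + 500)

    def test_constant_hr_recovered(self):
        tr = self.make_const_trace()
        series = hr_series(tr)
        conf = [e for e in series.estimates if e.confident]
        assert len(conf) >= 30
        assert all(abs(e.bpm - 72.0) <= 2.0 for e in conf)

    def test_estimate_time_grid(self):
        tr = self.make_const_trace(duration=40.0)
        cfg = PipelineConfig()
        series = hr_series(tr, cfg)
        expected = np.arange(cfg.window_s, 40.0 + 1e-9, cfg.hop_s)
        np.testing.assert_allclose(series.times, expected)

    def test_too_short_trace(self):
        tr = self.make_const_trace(duration=5.0)
        with pytest.raises(InputError):
            hr_series(tr, PipelineConfig())

    def test_orientation_invariance(self):
        """Axis permutations and sign flips change no estimate exactly."""
        tr = self.make_const_trace(orientation=tuple(TILTED))
        base = hr_series(tr)
        for xform in (
            lambda s: s[:, [1, 2, 0]],
            lambda s: s * np.array([-1.0, 1.0, -1.0]),
            lambda s: (s * np.array([1.0, -1.0, 1.0]))[:, [2, 1, 0]],
        ):
            other = hr_series(AccelTrace(tr.fs, tr.t0, xform(tr.samples)))
            assert [e.bpm for e in other.estimates] == [e.bpm for e in base.estimates]
            assert [e.confident for e in other.estimates] == [
                e.confident for e in base.estimates
            ]

    def test_amplitude_invariance(self):
        tr = self.make_const_trace(orientation=tuple(TILTED))
        base = hr_series(tr)
        scaled = hr_series(AccelTrace(tr.fs, tr.t0, 7.3 * tr.samples))
        np.testing.assert_allclose(
            [e.bpm for e in scaled.estimates], [e.bpm for e in base.estimates],
            rtol=1e-9,
        )

    def test_confident_estimates_stay_in_band(self):
        tr = self.make_const_trace()
        for est in hr_series(tr).estimates:
            if est.confident:
                assert 39.6 <= est.bpm <= 150.0

    def test_clip_bpm_option(self):
        from dataclasses import replace

        tr = self.make_const_trace()
        cfg = replace(PipelineConfig(), clip_bpm=True)
        for est in hr_series(tr, cfg).estimates:
            if est.confident:
                assert 45.0 <= est.bpm <= 150.0


class TestGapFilling:
    def test_short_gap_interpolated(self):
        tr = TestHRSeries().make_const_trace(duration=30.0)
        samples = tr.samples.copy()
        samples[100:105, 1] = np.nan  # 0.1 s gap
        filled = fill_gaps(AccelTrace(tr.fs, 0.0, samples))
        assert np.all(np.isfinite(filled.samples))

    def test_long_gap_rejected(self):
        tr = TestHRSeries().make_const_trace(duration=30.0)
        samples = tr.samples.copy()
        samples[100:130, 1] = np.nan  # 0.6 s gap
        with pytest.raises(InputError):
            fill_gaps(AccelTrace(tr.fs, 0.0, samples))
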