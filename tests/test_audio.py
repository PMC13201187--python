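"""Audio feature extraction: spectrogram arithmetic, centroid frequency,
autocorrelation respiration features and intensity statistics."""

import math

import numpy as np
import pytest

from bcgsleep import audio as aud
from bcgsleep.signal_io import AudioRecording

FS = 8000.0


def _tone(freq, duration=30.0, fs=FS, amp=0.5):
    t = np.arange(int(duration * fs)) / fs
    return AudioRecording(amp * np.sin(2 * np.pi * freq * t), fs)


def _breathing(period_s, duration=30.0, fs=FS, amp=0.3, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    t = np.arange(n) / fs
    env = np.clip(np.sin(2 * np.pi * t / period_s), 0, None) ** 2
    carrier = rng.standard_normal(n)
    return AudioRecording(amp * env * carrier + 0.001 * rng.standard_normal(n), fs)


class TestSpectrogram:
    def test_frame_count_arithmetic(self):
        n = int(30 * 44100)
        rec = AudioRecording(np.random.default_rng(0).standard_normal(n) * 0.1,
                             44100.0)
        _, times, power = aud.spectrogram(rec)
        assert power.shape[1] == (n - 2048) // 1024 + 1

    def test_pure_tone_peaks_in_matching_bin(self):
        freq, _, power = aud.spectrogram(_tone(1000.0))
        peak_bin = power.mean(axis=1).argmax()
        assert abs(freq[peak_bin] - 1000.0) < FS / 2048

    def test_silence_has_no_power(self):
        rec = AudioRecording(np.zeros(int(5 * FS)), FS)
        _, _, power = aud.spectrogram(rec)
        assert power.max() == pytest.approx(0.0, abs=1e-20)


class TestInstantaneousFrequency:
    def test_pure_tone_centroid_within_one_bin(self):
        freq, _, power = aud.spectrogram(_tone(440.0))
        finst = aud.instantaneous_frequency(freq, power)
        assert np.all(np.abs(finst - 440.0) < FS / 2048)

    def test_equal_tones_average(self):
        rec = _tone(200.0)
        rec2 = _tone(600.0)
        mix = AudioRecording(rec.samples + rec2.samples, FS)
        freq, _, power = aud.spectrogram(mix)
        finst = aud.instantaneous_frequency(freq, power)
        assert np.nanmean(finst) == pytest.approx(400.0, abs=15.0)

    def test_chirp_centroid_increases(self):
        t = np.arange(int(30 * FS)) / FS
        chirp = np.sin(2 * np.pi * (200 + 20 * t) * t)
        freq, _, power = aud.spectrogram(AudioRecording(chirp, FS))
        finst = aud.instantaneous_frequency(freq, power)
        assert np.all(np.diff(finst) > -5.0)  # monotone up to bin quantization
        assert finst[-1] > finst[0] + 300

    def test_centroid_bounded_by_powered_bins(self):
        rng = np.random.default_rng(1)
        rec = AudioRecording(0.2 * rng.standard_normal(int(5 * FS)), FS)
        freq, _, power = aud.spectrogram(rec)
        finst = aud.instantaneous_frequency(freq, power)
        assert np.all(finst >= freq[0]) and np.all(finst <= freq[-1])

    def test_zero_power_frame_flagged_nan(self):
        freq = np.array([0.0, 10.0, 20.0])
        power = np.zeros((3, 2))
        power[1, 0] = 1.0
        finst = aud.instantaneous_frequency(freq, power)
        assert finst[0] == 10.0
        assert np.isnan(finst[1])


class TestAutocorrelation:
    def test_lag_zero_is_exactly_one(self):
        rng = np.random.default_rng(2)
        r = aud.autocorrelation(rng.standard_normal(100))
        assert r[0] == 1.0

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            r = aud.autocorrelation(rng.standard_normal(200))
            assert np.all(r <= 1.0 + 1e-12) and np.all(r >= -1.0 - 1e-12)

    def test_periodic_envelope_peaks_at_period(self):
        period = 25
        y = np.tile(np.arange(period, dtype=float), 8)  # sawtooth
        r = aud.autocorrelation(y)
        assert r[period] > r[period - 5] and r[period] > r[period + 5]

    def test_matches_literal_double_loop(self):
        rng = np.random.default_rng(4)
        y = list(rng.standard_normal(10))
        T = len(y)
        ybar = sum(y) / T
        c = [sum((y[t] - ybar) * (y[t + k] - ybar) for t in range(T - k)) / T
             for k in range(T)]
        expected = np.array(c) / c[0]
        np.testing.assert_allclose(aud.autocorrelation(np.array(y)), expected,
                                   rtol=1e-9, atol=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            aud.autocorrelation(np.full(10, 3.0))


class TestRespirationCycle:
    def test_four_second_breathing_recovered(self):
        feats = aud.segment_respiration_features(_breathing(4.0))
        assert feats.detected
        assert feats.cp == pytest.approx(4.0, abs=0.25)
        assert feats.ci > 0.3

    def test_white_noise_rarely_detected(self):
        rng = np.random.default_rng(5)
        detected = 0
        for seed in range(40):
            n = int(30 * FS)
            rec = AudioRecording(0.1 * rng.standard_normal(n), FS)
            if aud.segment_respiration_features(rec).detected:
                detected += 1
        assert detected <= 2  # >= 95% of seeds undetected

    def test_equal_peak_amplitudes_give_zero_consistency(self):
        fr = 10.0
        lags = np.arange(400) / fr
        r = 0.5 * np.cos(2 * np.pi * lags / 4.0) * np.exp(-lags * 1e-9)
        r[0] = 1.0
        feats = aud.respiration_cycle_features(r, fr)
        assert feats.detected
        assert feats.cc == pytest.approx(0.0, abs=1e-6)

    def test_literal_frame_product_flag(self):
        feats = aud.segment_respiration_features(
            _breathing(4.0), literal_period_product=True)
        fr = FS / aud.HOP
        assert feats.cp == pytest.approx(4.0 * fr * fr, rel=0.1)


class TestAcousticStats:
    def test_silence_sits_at_spl_floor_with_zero_energy(self):
        rec = AudioRecording(np.zeros(int(30 * FS)), FS)
        s = aud.acoustic_stats(rec)
        assert s.spl_mean == aud.SPL_FLOOR_DB
        assert s.total_energy == pytest.approx(0.0, abs=1e-20)

    def test_doubling_amplitude_adds_six_db(self):
        rec = _breathing(4.0, seed=6)
        loud = AudioRecording(2.0 * rec.samples, FS)
        a, b = aud.acoustic_stats(rec), aud.acoustic_stats(loud)
        assert b.spl_mean - a.spl_mean == pytest.approx(20 * math.log10(2),
                                                        abs=1e-6)
        assert b.total_energy == pytest.approx(4.0 * a.total_energy, rel=1e-6)

    def test_scaling_leaves_centroid_and_period_unchanged(self):
        rec = _breathing(4.0, seed=7)
        loud = AudioRecording(3.0 * rec.samples, FS)
        a, b = aud.acoustic_stats(rec), aud.acoustic_stats(loud)
        assert b.instfreq_mean == pytest.approx(a.instfreq_mean, rel=1e-9)
        fa = aud.segment_respiration_features(rec)
        fb = aud.segment_respiration_features(loud)
        assert fb.cp == pytest.approx(fa.cp)

    def test_band_energies_sum_to_total_within_tolerance(self):
        rec = _breathing(4.0, seed=8)
        s = aud.acoustic_stats(rec)
        assert s.band_energies.sum() <= s.total_energy * (1 + 1e-9)
        assert s.band_energies.sum() >= s.total_energy * 0.95

    def test_snore_raises_low_band_share(self):
        rng = np.random.default_rng(9)
        quiet = _breathing(4.0, seed=10)
        t = np.arange(quiet.samples.size) / FS
        snore = quiet.samples + 0.3 * np.sin(2 * np.pi * 90 * t) \
            * np.clip(np.sin(2 * np.pi * t / 4.0), 0, None)
        loud = AudioRecording(snore, FS)
        a, b = aud.acoustic_stats(quiet), aud.acoustic_stats(loud)
        low_a = (a.band_energies[0] + a.band_energies[1]) / a.total_energy
        low_b = (b.band_energies[0] + b.band_energies[1]) / b.total_energy
        assert low_b > low_a


class TestNoiseGate:
    def test_stationary_hum_attenuated_tone_kept(self):
        rng = np.random.default_rng(11)
        n = int(20 * FS)
        t = np.arange(n) / FS
        hum = 0.2 * np.sin(2 * np.pi * 60 * t)
        tone = 0.3 * np.sin(2 * np.pi * 1000 * t)
        rec = AudioRecording(hum + tone, FS)
        profile = AudioRecording(hum[: int(5 * FS)], FS)
        gated = aud.noise_gate(rec, profile)

        def band_power(x, lo, hi):
            freq, _, p = aud.spectrogram(AudioRecording(x, FS))
            m = (freq >= lo) & (freq < hi)
            return p[m].sum()

        hum_drop = 10 * math.log10(
            band_power(rec.samples, 40, 80) / band_power(gated.samples, 40, 80))
        tone_drop = 10 * math.log10(
            band_power(rec.samples, 950, 1050)
            / max(band_power(gated.samples, 950, 1050), 1e-30))
        assert hum_drop >= 10.0
        assert tone_drop < 3.0
        assert gated.samples.size == rec.samples.size

    def test_zero_profile_is_identity_up_to_reconstruction(self):
        rng = np.random.default_rng(12)
        rec = AudioRecording(0.2 * rng.standard_normal(int(10 * FS)), FS)
        profile = AudioRecording(np.zeros(int(2 * FS)), FS)
        gated = aud.noise_gate(rec, profile)
        err = np.abs(gated.samples - rec.samples)[2048:-2048]
        assert err.max() < 1e-8

    def test_profile_equal_to_signal_silences_output(self):
        t = np.arange(int(10 * FS)) / FS
        hum = 0.3 * np.sin(2 * np.pi * 120 * t)
        rec = AudioRecording(hum, FS)
        gated = aud.noise_gate(rec, rec)
        assert np.sqrt(np.mean(gated.samples ** 2)) < \
            0.1 * np.sqrt(np.mean(rec.samples ** 2))

    def test_profile_longer_than_recording_rejected(self):
        rec = AudioRecording(np.zeros(1000), FS)
        profile = AudioRecording(np.zeros(2000), FS)
        with pytest.raises(ValueError):
            aud.noise_gate(rec, profile)
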