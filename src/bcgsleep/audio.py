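"""Respiration-related features from bedside audio.

A 2048-sample Hanning spectrogram at 50% overlap feeds three feature
families per 30-s segment: the spectral-centroid instantaneous frequency,
autocorrelation-based respiration cycle features (period, intensity,
consistency) computed on a band-limited breathing envelope, and acoustic
intensity statistics (band energies and sound pressure levels in dBFS).

The breathing envelope is the rectified, 2 Hz low-passed waveform sampled
at the spectrogram frame rate F_r = sample_rate / 1024 (about 43.07
frames/s at 44.1 kHz); breath periods of 3-8 s cannot be read off raw
44.1 kHz samples, but the envelope carries them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from bcgsleep.signal_io import AudioRecording

FRAME_LEN = 2048
HOP = 1024
SPL_FLOOR_DB = -120.0

#: spectral energy bands (Hz); the last band is truncated at Nyquist
ENERGY_BANDS = ((0, 100), (100, 300), (300, 800), (800, 2000), (2000, 8000))

# physiologic breath periods: 4-40 breaths/min
MIN_BREATH_LAG_S = 1.5
MAX_BREATH_LAG_S = 15.0
PEAK_PROMINENCE = 0.1
# short 30-s envelopes fluctuate at ~1/sqrt(N); a height floor keeps the
# false-detection rate on unstructured noise below a few percent
PEAK_MIN_HEIGHT = 0.25


@dataclasses.dataclass
class RespirationAudioFeatures:
    cp: float        # respiration cycle period, s
    ci: float        # cycle intensity: autocorrelation at the first peak
    cc: float        # cycle consistency: SD of all peak amplitudes
    detected: bool
    n_peaks: int = 0


@dataclasses.dataclass
class AcousticStats:
    instfreq_mean: float
    instfreq_sd: float
    instfreq_median: float
    instfreq_iqr: float
    band_energies: np.ndarray  # one per ENERGY_BANDS entry
    total_energy: float
    spl_mean: float
    spl_max: float
    spl_sd: float
    spl_rms: float


def spectrogram(a: AudioRecording) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time power spectrum: 2048-sample Hanning frames, hop 1024.

    Returns (freq Hz, frame times s, power[freq, frame]); frame count is
    floor((N - 2048)/1024) + 1.
    """
    if a.samples.size < FRAME_LEN:
        raise ValueError("audio segment shorter than one 2048-sample frame")
    freq, times, power = sps.spectrogram(
        a.samples, fs=a.sample_rate, window=np.hanning(FRAME_LEN),
        nperseg=FRAME_LEN, noverlap=FRAME_LEN - HOP, detrend=False,
        scaling="spectrum", mode="psd")
    return freq, times, power


def instantaneous_frequency(freq: np.ndarray, power: np.ndarray) -> np.ndarray:
    """Per-frame spectral centroid, sum(f P)/sum(P); NaN on dead frames."""
    total = power.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        centroid = (freq[:, None] * power).sum(axis=0) / total
    centroid[total <= 0] = np.nan
    return centroid


def autocorrelation(y) -> np.ndarray:
    """Biased-normalized autocorrelation r_k = c_k / c_0 with
    c_k = (1/T) sum_{t} (y_t - ybar)(y_{t+k} - ybar); r_0 = 1 exactly."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("autocorrelation needs at least 2 samples")
    yc = y - y.mean()
    c0 = float(np.dot(yc, yc))
    if c0 == 0:
        raise ValueError("zero-variance series: autocorrelation undefined")
    full = np.correlate(yc, yc, mode="full")[y.size - 1:]
    return full / c0


def breathing_envelope(a: AudioRecording, cutoff_hz: float = 2.0,
                       hop: int = HOP) -> tuple[np.ndarray, float]:
    """Rectify, low-pass and decimate to the spectrogram frame rate.

    Returns (envelope, frame_rate).
    """
    rect = np.abs(a.samples)
    nyq = a.sample_rate / 2.0
    b, co = sps.butter(2, cutoff_hz / nyq)
    smooth = sps.filtfilt(b, co, rect)
    env = smooth[::hop]
    return env, a.sample_rate / hop


def respiration_cycle_features(r: np.ndarray, frame_rate: float,
                               prominence: float = PEAK_PROMINENCE,
                               min_height: float = PEAK_MIN_HEIGHT,
                               min_lag_s: float = MIN_BREATH_LAG_S,
                               max_lag_s: float = MAX_BREATH_LAG_S,
                               literal_period_product: bool = False
                               ) -> RespirationAudioFeatures:
    """Cycle period/intensity/consistency from the envelope autocorrelation.

    Positive peaks of r within physiologic lags, with amplitude at least
    ``min_height`` and prominence at least ``prominence``, are located; the
    first peak lag t1 gives the period in seconds (t1 / F_r; the raw
    frame-count product is available via ``literal_period_product``), its
    amplitude the intensity, and the SD of all peak amplitudes the
    consistency.  With no qualifying peak the features are flagged
    undetected.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    lo = max(1, int(np.ceil(min_lag_s * frame_rate)))
    hi = min(r.size - 1, int(np.floor(max_lag_s * frame_rate)))
    if hi <= lo:
        return RespirationAudioFeatures(np.nan, np.nan, np.nan, False)
    segment = r[: hi + 1]
    peaks, _ = sps.find_peaks(segment, prominence=prominence,
                              height=min_height)
    peaks = peaks[peaks >= lo]
    if peaks.size == 0:
        return RespirationAudioFeatures(np.nan, np.nan, np.nan, False)
    t1 = int(peaks[0])
    cp = float(t1 * frame_rate) if literal_period_product else float(t1 / frame_rate)
    ci = float(r[t1])
    cc = float(np.std(r[peaks]))
    return RespirationAudioFeatures(cp, ci, cc, True, n_peaks=int(peaks.size))


def segment_respiration_features(a: AudioRecording, **kwargs
                                 ) -> RespirationAudioFeatures:
    """Respiration cycle features of one audio segment via its envelope."""
    env, fr = breathing_envelope(a)
    try:
        r = autocorrelation(env)
    except ValueError:
        return RespirationAudioFeatures(np.nan, np.nan, np.nan, False)
    return respiration_cycle_features(r, fr, **kwargs)


def acoustic_stats(a: AudioRecording, spl_frame_s: float = 0.1) -> AcousticStats:
    """Instantaneous-frequency summary, band energies and SPL statistics.

    Energies are summed spectrogram power per band (bands truncated at
    Nyquist); SPL is 20*log10(RMS) per 100-ms frame in dB relative to
    digital full scale, floored at -120 dB.
    """
    freq, _, power = spectrogram(a)
    finst = instantaneous_frequency(freq, power)
    finst = finst[np.isfinite(finst)]
    if finst.size:
        q75, q25 = np.percentile(finst, [75, 25])
        if_stats = (float(np.mean(finst)), float(np.std(finst)),
                    float(np.median(finst)), float(q75 - q25))
    else:
        if_stats = (np.nan, np.nan, np.nan, np.nan)

    energies = []
    for lo, hi in ENERGY_BANDS:
        m = (freq >= lo) & (freq < hi)
        energies.append(float(power[m].sum()))
    total = float(power.sum())

    n = max(1, int(round(spl_frame_s * a.sample_rate)))
    n_frames = a.samples.size // n
    if n_frames == 0:
        rms = np.sqrt(np.mean(a.samples ** 2)) if a.samples.size else 0.0
        frames_rms = np.array([rms])
    else:
        frames = a.samples[: n_frames * n].reshape(n_frames, n)
        frames_rms = np.sqrt(np.mean(frames ** 2, axis=1))
    with np.errstate(divide="ignore"):
        spl = 20.0 * np.log10(frames_rms)
    spl = np.maximum(spl, SPL_FLOOR_DB)
    overall = np.sqrt(np.mean(a.samples ** 2))
    spl_rms = max(20.0 * np.log10(overall), SPL_FLOOR_DB) if overall > 0 else SPL_FLOOR_DB
    return AcousticStats(*if_stats, np.array(energies), total,
                         float(np.mean(spl)), float(np.max(spl)),
                         float(np.std(spl)), float(spl_rms))


def noise_gate(a: AudioRecording, noise_profile: AudioRecording,
               attenuation_floor: float = 0.05) -> AudioRecording:
    """Spectral-subtraction gate using the profile's per-bin noise floor.

    The profile's mean STFT magnitude per bin is subtracted from the
    recording's STFT magnitudes (floored at ``attenuation_floor`` times the
    original); the original phase is kept and the signal resynthesized at
    its input length.
    """
    if noise_profile.samples.size > a.samples.size:
        raise ValueError("noise profile longer than the recording")
    if noise_profile.samples.size < FRAME_LEN:
        raise ValueError("noise profile shorter than one analysis frame")
    win = np.hanning(FRAME_LEN)
    _, _, prof = sps.stft(noise_profile.samples, fs=a.sample_rate, window=win,
                          nperseg=FRAME_LEN, noverlap=FRAME_LEN - HOP)
    floor = np.abs(prof).mean(axis=1, keepdims=True)
    _, _, Z = sps.stft(a.samples, fs=a.sample_rate, window=win,
                       nperseg=FRAME_LEN, noverlap=FRAME_LEN - HOP)
    mag = np.abs(Z)
    gated = np.maximum(mag - floor, attenuation_floor * mag)
    with np.errstate(invalid="ignore", divide="ignore"):
        phase = np.where(mag > 0, Z / mag, 0.0)
    _, out = sps.istft(gated * phase, fs=a.sample_rate, window=win,
                       nperseg=FRAME_LEN, noverlap=FRAME_LEN - HOP)
    out = out[: a.samples.size]
    if out.size < a.samples.size:
        out = np.pad(out, (0, a.samples.size - out.size))
    return AudioRecording(out, a.sample_rate)
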