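"""Cardiopulmonary coupling (CPC) between the JJ tachogram and respiration.

Both signals are cubic-spline resampled to 2 Hz.  Each 1024-sample (512 s)
window is split into three 512-sample sub-windows at offsets 0/256/512;
each sub-window is linearly detrended, Hanning-windowed and Fourier
transformed.  Cross- and auto-spectra are averaged across sub-windows, the
magnitude-squared coherence C_xy = |P_xy|^2 / (P_xx P_yy) computed from the
averages, and the per-frequency CPC index is |P_xy|^2 * C_xy.  Sub-window
averaging is what makes the coherence informative: a single segment gives
C identically 1.

Band features integrate the CPC index over LF (0.01-0.10 Hz) and
HF (0.10-0.40 Hz), the bands used by the CPC literature this method
follows.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from bcgsleep.preprocessing import resample_uniform
from bcgsleep.signal_io import EPOCH_S, Session

CPC_FS = 2.0              # Hz
CPC_WINDOW = 1024         # samples (512 s)
CPC_SUBWINDOW = 512       # samples
CPC_SUBSTEP = 256         # samples (50% overlap, 3 sub-windows per window)
CPC_LF_BAND = (0.01, 0.10)
CPC_HF_BAND = (0.10, 0.40)


@dataclasses.dataclass
class CPCSpectrum:
    freq: np.ndarray
    cross_power: np.ndarray   # |P_xy|^2
    coherence: np.ndarray     # C_xy in [0, 1]
    cpc: np.ndarray           # |P_xy|^2 * C_xy
    partial: bool = False


@dataclasses.dataclass
class CPCFeatures:
    lf_power: float
    hf_power: float
    lf_hf_ratio: float
    total_power: float
    partial: bool = False


def _averaged_spectra(x: np.ndarray, y: np.ndarray, fs: float,
                      nperseg: int, step: int):
    """Sub-window averaged auto-/cross-spectra (detrend + Hanning per seg)."""
    n = x.size
    starts = range(0, n - nperseg + 1, step)
    win = np.hanning(nperseg)
    pxx = pyy = pxy = None
    count = 0
    t = np.arange(nperseg)
    for s in starts:
        xs, ys = x[s:s + nperseg], y[s:s + nperseg]
        # least-squares line removal per sub-window
        cx = np.polyfit(t, xs, 1)
        cy = np.polyfit(t, ys, 1)
        xs = (xs - np.polyval(cx, t)) * win
        ys = (ys - np.polyval(cy, t)) * win
        X = np.fft.rfft(xs)
        Y = np.fft.rfft(ys)
        if pxx is None:
            pxx = np.abs(X) ** 2
            pyy = np.abs(Y) ** 2
            pxy = X * np.conj(Y)
        else:
            pxx += np.abs(X) ** 2
            pyy += np.abs(Y) ** 2
            pxy += X * np.conj(Y)
        count += 1
    if count == 0:
        raise ValueError("segment shorter than one sub-window")
    freq = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    # normalization constants cancel in the coherence; keep spectra scaled
    # per Welch convention so cross power carries physical units
    scale = 1.0 / (fs * np.sum(win ** 2) * count)
    return freq, pxx * scale, pyy * scale, pxy * scale, count


def cpc_window(jj_2hz, bdr_2hz, fs: float = CPC_FS,
               nperseg: int = CPC_SUBWINDOW, step: int = CPC_SUBSTEP,
               partial: bool = False) -> CPCSpectrum:
    """CPC spectrum of one (nominally 1024-sample) window pair.

    Constant (zero-power) inputs yield coherence 0 at the dead frequencies
    rather than a division error.
    """
    x = np.asarray(jj_2hz, dtype=float)
    y = np.asarray(bdr_2hz, dtype=float)
    if x.shape != y.shape:
        raise ValueError("segments must share one time support")
    freq, pxx, pyy, pxy, _ = _averaged_spectra(x, y, fs, nperseg, step)
    cross = np.abs(pxy) ** 2
    # a (near-)constant segment has no fluctuation power: its coherence is
    # undefined and reported as 0 rather than the numerical-residue ratio
    tiny_x = x.var() <= (1e-12 * (1.0 + np.abs(x).max())) ** 2
    tiny_y = y.var() <= (1e-12 * (1.0 + np.abs(y).max())) ** 2
    if tiny_x or tiny_y:
        zeros = np.zeros_like(pxx)
        return CPCSpectrum(freq, zeros, zeros.copy(), zeros.copy(), partial)
    denom = pxx * pyy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, cross / np.where(denom > 0, denom, 1.0), 0.0)
    coh = np.clip(coh, 0.0, 1.0)
    return CPCSpectrum(freq, cross, coh, cross * coh, partial)


def band_features(spec: CPCSpectrum,
                  lf_band=CPC_LF_BAND, hf_band=CPC_HF_BAND) -> CPCFeatures:
    """Integrate the CPC index over the LF/HF bands."""

    def integrate(lo, hi):
        m = (spec.freq >= lo) & (spec.freq < hi)
        return float(np.trapezoid(spec.cpc[m], spec.freq[m])) if m.sum() > 1 else 0.0

    lf = integrate(*lf_band)
    hf = integrate(*hf_band)
    total = float(np.trapezoid(spec.cpc, spec.freq))
    return CPCFeatures(lf, hf, lf / hf if hf > 0 else np.nan, total, spec.partial)


def session_tachograms(session: Session, fs: float = CPC_FS
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2 Hz JJ tachogram and zero-mean respiration waveform on one grid.

    The 1 Hz BDR series is mean-removed (a spectral estimator needs a
    fluctuation signal, not a rate level) before resampling.
    """
    b, v = session.beat_series, session.vitals
    t_jj, jj = resample_uniform(b.onset_times, b.intervals, fs)
    bdr = v.bdr - np.nanmean(v.bdr)
    bdr = np.nan_to_num(bdr, nan=0.0)
    t_b, bdr2 = resample_uniform(v.t, bdr, fs)
    t0 = max(t_jj[0], t_b[0])
    t1 = min(t_jj[-1], t_b[-1])
    m_jj = (t_jj >= t0) & (t_jj <= t1)
    m_b = (t_b >= t0) & (t_b <= t1)
    n = min(m_jj.sum(), m_b.sum())
    return t_jj[m_jj][:n], jj[m_jj][:n], bdr2[m_b][:n]


def cpc_series(session: Session, window: int = CPC_WINDOW,
               lf_band=CPC_LF_BAND, hf_band=CPC_HF_BAND) -> list[CPCFeatures]:
    """Per-epoch CPC band features; the 512-s window ends at each epoch's end.

    Early epochs whose full window would precede the session start are
    computed on the truncated segment (flagged partial) provided it still
    holds at least one 512-sample sub-window; shorter segments yield NaN
    features.
    """
    t, jj, bdr = session_tachograms(session)
    n_epochs = session.n_epochs
    if t.size < CPC_SUBWINDOW:
        raise ValueError("session too short for CPC analysis")
    fs = CPC_FS
    out: list[CPCFeatures] = []
    for k in range(n_epochs):
        end_t = (k + 1) * EPOCH_S
        i_end = int(round((min(end_t, t[-1] + 1.0 / fs) - t[0]) * fs))
        i_end = min(i_end, t.size)
        i_start = i_end - window
        partial = i_start < 0
        i_start = max(i_start, 0)
        if i_end - i_start < CPC_SUBWINDOW:
            out.append(CPCFeatures(np.nan, np.nan, np.nan, np.nan, partial=True))
            continue
        spec = cpc_window(jj[i_start:i_end], bdr[i_start:i_end], partial=partial)
        out.append(band_features(spec, lf_band, hf_band))
    return out
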