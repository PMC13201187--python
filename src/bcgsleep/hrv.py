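"""Heart-rate-variability features over 5-min analysis windows.

Time domain (SDNN, RMSSD, pNN50), frequency domain (LF/HF band powers of
the resampled JJ tachogram), Poincaré geometry (SD1/SD2) and asymmetry
indices (Porta, Guzik, Ehlers, phase, area), sequential trend analysis
quadrant statistics, sample/approximate entropy, detrended fluctuation
analysis, Rényi entropy of embedded beat subsequences, and the device-style
respiration-depth HRV derived from stroke-volume fluctuation.

Conventions: the Poincaré plot scatters (JJ_i, JJ_{i+1}); the line of
identity (LOI) is the diagonal y = x; points above the LOI are beat-to-beat
decelerations.  All indices that are ratios of counts or distances exclude
points lying exactly on the LOI.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import signal as sps

from bcgsleep.preprocessing import lowpass_smooth, resample_uniform

# Short-term HRV band edges (Hz), per the HRV task-force standards.
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

TACHOGRAM_FS = 4.0  # Hz; JJ series resampling rate for spectral analysis


class InsufficientData(ValueError):
    """Raised when a window holds too few valid beats for a feature."""


@dataclasses.dataclass
class HRVTimeFeatures:
    mean_jj: float
    sdnn: float
    rmssd: float
    pnn50: float
    cv_jj: float


@dataclasses.dataclass
class HRVFreqFeatures:
    lf_power: float
    hf_power: float
    lf_hf_ratio: float
    total_power: float
    lf_nu: float
    hf_nu: float


@dataclasses.dataclass
class PoincareFeatures:
    sd1: float
    sd2: float
    sd1_sd2_ratio: float
    porta_pct: float
    guzik_pct: float
    ehler_index: float
    phase_index: float
    area_index: float


@dataclasses.dataclass
class STAFeatures:
    q_dist: np.ndarray      # mean Eq.-style distance per quadrant Q1..Q4
    q_occupancy: np.ndarray  # fraction of off-axis pairs per quadrant
    degenerate: bool


@dataclasses.dataclass
class DeviceHRVFeatures:
    rdepth: float
    hrv_rdepth: float


def time_domain(jj) -> HRVTimeFeatures:
    """SDNN, RMSSD, pNN50 and the coefficient of variation of JJ intervals."""
    jj = np.asarray(jj, dtype=float)
    if jj.size < 2:
        raise InsufficientData("time-domain HRV needs >= 2 intervals")
    diffs = np.diff(jj)
    mean_jj = float(np.mean(jj))
    sdnn = float(np.std(jj, ddof=1))
    rmssd = float(np.sqrt(np.mean(diffs ** 2)))
    pnn50 = float(np.mean(np.abs(diffs) > 50.0))
    return HRVTimeFeatures(mean_jj, sdnn, rmssd, pnn50,
                           sdnn / mean_jj if mean_jj else np.nan)


def freq_domain(onsets, jj,
                lf_band=LF_BAND, hf_band=HF_BAND,
                fs: float = TACHOGRAM_FS) -> HRVFreqFeatures:
    """Band powers of the uniformly resampled, detrended JJ tachogram.

    The irregular beat series is cubic-spline resampled to ``fs`` Hz and the
    spectrum estimated by Welch's method with 120-s Hanning segments at 50%
    overlap (shorter windows fall back to one full-length segment).
    """
    onsets = np.asarray(onsets, dtype=float)
    jj = np.asarray(jj, dtype=float)
    if onsets.size < 4 or onsets[-1] - onsets[0] < 120.0:
        raise InsufficientData("frequency-domain HRV needs >= 120 s of beats")
    _, tach = resample_uniform(onsets, jj, fs)
    tach = sps.detrend(tach)
    nperseg = min(int(120 * fs), tach.size)
    freq, psd = sps.welch(tach, fs=fs, window="hann", nperseg=nperseg,
                          noverlap=nperseg // 2, detrend="linear")

    def band_power(lo, hi):
        m = (freq >= lo) & (freq < hi)
        return float(np.trapezoid(psd[m], freq[m])) if m.sum() > 1 else 0.0

    lf = band_power(*lf_band)
    hf = band_power(*hf_band)
    total = band_power(freq[0], float(freq[-1]) + 1e-12)
    denom = lf + hf
    return HRVFreqFeatures(
        lf_power=lf, hf_power=hf,
        lf_hf_ratio=lf / hf if hf > 0 else np.nan,
        total_power=total,
        lf_nu=lf / denom if denom > 0 else np.nan,
        hf_nu=hf / denom if denom > 0 else np.nan,
    )


def poincare_sd(jj) -> tuple[float, float]:
    """SD1/SD2: dispersion perpendicular to / along the line of identity.

    SD1 = SD(JJ_{i+1} - JJ_i)/sqrt(2), SD2 = SD(JJ_{i+1} + JJ_i)/sqrt(2).
    """
    jj = np.asarray(jj, dtype=float)
    if jj.size < 3:
        raise InsufficientData("Poincaré features need >= 3 intervals")
    x, y = jj[:-1], jj[1:]
    sd1 = float(np.std(y - x, ddof=1) / np.sqrt(2.0))
    sd2 = float(np.std(y + x, ddof=1) / np.sqrt(2.0))
    return sd1, sd2


def asymmetry_indices(jj) -> tuple[float, float, float, float, float]:
    """Porta, Guzik, Ehlers, phase and area asymmetry of the Poincaré cloud.

    Porta: percentage of off-LOI points below the LOI.  Guzik: percentage of
    the total LOI-distance carried by points above it.  Ehlers: skewness
    statistic of successive differences, sum(d^3)/sum(d^2)^(3/2).  Phase:
    mean angular deviation (degrees) from the 45-degree LOI over above-LOI
    points.  Area: percentage of the summed circular-sector areas (1/2 r^2
    |dtheta|) contributed by above-LOI points.
    """
    jj = np.asarray(jj, dtype=float)
    if jj.size < 3:
        raise InsufficientData("asymmetry indices need >= 3 intervals")
    x, y = jj[:-1], jj[1:]
    d = y - x
    off = d != 0
    if not np.any(off):
        raise InsufficientData("all Poincaré points on the line of identity")
    below = d < 0
    above = d > 0
    porta = 100.0 * below.sum() / off.sum()

    dist = np.abs(d) / np.sqrt(2.0)  # perpendicular distance to the LOI
    guzik = 100.0 * dist[above].sum() / dist[off].sum()

    d2 = d[off]
    ehler = float(np.sum(d2 ** 3) / np.sum(d2 ** 2) ** 1.5)

    theta = np.degrees(np.arctan2(y, x)) - 45.0  # deviation from the LOI
    phase = float(np.mean(theta[above])) if above.any() else np.nan

    r2 = x ** 2 + y ** 2
    sector = 0.5 * r2 * np.abs(np.radians(theta))
    area = 100.0 * sector[above].sum() / sector[off].sum() if sector[off].sum() > 0 else np.nan
    return float(porta), float(guzik), ehler, phase, float(area)


def sta_features(jj) -> STAFeatures:
    """Sequential trend analysis on successive-difference pairs.

    Pairs (dJJ_n, dJJ_{n+1}) are assigned to quadrants by sign (Q1 both
    positive ... Q4 x>0, y<0); each quadrant reports the mean radial
    distance sqrt(a_n^2 + a_{n+1}^2) of its pairs and its occupancy among
    off-axis pairs.  Pairs with a zero component belong to no quadrant.
    """
    jj = np.asarray(jj, dtype=float)
    if jj.size < 4:
        raise InsufficientData("STA needs >= 4 intervals")
    d = np.diff(jj)
    a, b = d[:-1], d[1:]
    dist = np.sqrt(a ** 2 + b ** 2)
    quadrants = [
        (a > 0) & (b > 0),
        (a < 0) & (b > 0),
        (a < 0) & (b < 0),
        (a > 0) & (b < 0),
    ]
    n_off = sum(int(q.sum()) for q in quadrants)
    q_dist = np.array([float(dist[q].mean()) if q.any() else 0.0 for q in quadrants])
    if n_off == 0:
        return STAFeatures(q_dist, np.zeros(4), degenerate=True)
    occ = np.array([q.sum() / n_off for q in quadrants], dtype=float)
    return STAFeatures(q_dist, occ, degenerate=False)


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    n = x.size - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


def renyi_entropy(jj, alpha: float, embed_m: int = 2,
                  sigma: Optional[float] = None) -> float:
    """Order-``alpha`` Rényi entropy (bits) of a density over embedded beats.

    Each length-``embed_m`` subsequence gets a Gaussian-kernel density
    estimate from its squared Euclidean distances to all subsequences; the
    densities are normalized to a probability vector rho and
    H_alpha = log2(sum rho^alpha) / (1 - alpha), with alpha = 1 routed to
    the Shannon limit.  ``sigma`` defaults to the standard deviation of the
    pairwise embedded distances.
    """
    if alpha <= 0:
        raise ValueError("entropy order alpha must be positive")
    jj = np.asarray(jj, dtype=float)
    if jj.size <= embed_m:
        raise InsufficientData("series shorter than the embedding length")
    emb = _embed(jj, embed_m)
    diff = emb[:, None, :] - emb[None, :, :]
    sq = np.sum(diff ** 2, axis=-1)
    if sigma is None:
        d = np.sqrt(sq[np.triu_indices(sq.shape[0], k=1)])
        sigma = float(np.std(d)) if d.size else 0.0
        if sigma == 0.0:
            sigma = 1.0  # degenerate (constant) series: uniform density
    if sigma <= 0:
        raise ValueError("kernel width sigma must be positive")
    rho = np.sum(np.exp(-sq / (2.0 * sigma ** 2)), axis=1) / (sigma * np.sqrt(2 * np.pi))
    rho = rho / rho.sum()
    if abs(alpha - 1.0) < 1e-12:
        return float(-np.sum(rho * np.log2(rho)))
    return float(np.log2(np.sum(rho ** alpha)) / (1.0 - alpha))


def renyi_profile(jj, alphas, embed_m: int = 2,
                  sigma: Optional[float] = None) -> dict[float, float]:
    """Rényi entropies for several orders sharing one density estimate.

    Equivalent to calling :func:`renyi_entropy` per order but computes the
    kernel density once.
    """
    jj = np.asarray(jj, dtype=float)
    if jj.size <= embed_m:
        raise InsufficientData("series shorter than the embedding length")
    emb = _embed(jj, embed_m)
    diff = emb[:, None, :] - emb[None, :, :]
    sq = np.sum(diff ** 2, axis=-1)
    if sigma is None:
        d = np.sqrt(sq[np.triu_indices(sq.shape[0], k=1)])
        sigma = float(np.std(d)) if d.size else 0.0
        if sigma == 0.0:
            sigma = 1.0
    rho = np.sum(np.exp(-sq / (2.0 * sigma ** 2)), axis=1) / (sigma * np.sqrt(2 * np.pi))
    rho = rho / rho.sum()
    out = {}
    for alpha in alphas:
        if alpha <= 0:
            raise ValueError("entropy order alpha must be positive")
        if abs(alpha - 1.0) < 1e-12:
            out[alpha] = float(-np.sum(rho * np.log2(rho)))
        else:
            out[alpha] = float(np.log2(np.sum(rho ** alpha)) / (1.0 - alpha))
    return out


def sample_approx_entropy(jj, m: int = 2, r: float = 0.2
                          ) -> tuple[float, float]:
    """Sample and approximate entropy with tolerance ``r`` times the SD.

    SampEn excludes self-matches (infinite when no template matches, flagged
    by the inf value); ApEn includes them.  Chebyshev distance throughout.
    """
    jj = np.asarray(jj, dtype=float)
    n = jj.size
    if n < 2 * (m + 1):
        raise InsufficientData("entropy needs a longer series")
    tol = r * np.std(jj)
    if tol == 0:
        return 0.0, 0.0  # constant series: every template matches

    def counts(mm: int):
        templates = _embed(jj, mm)
        dist = np.max(np.abs(templates[:, None, :] - templates[None, :, :]), axis=-1)
        match = dist <= tol
        return match

    match_m = counts(m)
    match_m1 = counts(m + 1)

    # SampEn: pair counts excluding self-matches, over the same n-m templates
    nm = match_m1.shape[0]
    b = match_m[:nm, :nm].sum() - nm
    a = match_m1.sum() - nm
    sampen = float(-np.log(a / b)) if a > 0 and b > 0 else float("inf")

    # ApEn: log-average of per-template match frequencies incl. self
    phi_m = np.mean(np.log(match_m.mean(axis=1)))
    phi_m1 = np.mean(np.log(match_m1.mean(axis=1)))
    apen = float(phi_m - phi_m1)
    return sampen, apen


def dfa(jj, scale_ranges=((4, 16), (16, 64))) -> tuple[float, float]:
    """Detrended fluctuation analysis slopes over short/long box ranges.

    The mean-centered series is integrated, split into non-overlapping boxes
    of each size, linearly detrended per box, and the RMS fluctuation F(n)
    regressed against box size on log-log axes.  Returns (alpha1, alpha2);
    alpha2 is NaN when the series is too short for the long-range boxes.
    """
    jj = np.asarray(jj, dtype=float)
    if jj.size < 4 * scale_ranges[0][0]:
        raise InsufficientData("series too short for DFA")
    profile = np.cumsum(jj - np.mean(jj))

    def fluctuation(box: int) -> float:
        n_boxes = profile.size // box
        if n_boxes < 2:
            return np.nan
        segs = profile[: n_boxes * box].reshape(n_boxes, box)
        t = np.arange(box)
        # per-box least-squares line removal
        tc = t - t.mean()
        denom = np.sum(tc ** 2)
        slopes = segs @ tc / denom
        resid = segs - segs.mean(axis=1, keepdims=True) - slopes[:, None] * tc
        return float(np.sqrt(np.mean(resid ** 2)))

    def slope(lo: int, hi: int) -> float:
        boxes = np.unique(np.round(np.geomspace(lo, hi, 10)).astype(int))
        fs = np.array([fluctuation(b) for b in boxes])
        ok = np.isfinite(fs) & (fs > 0)
        if ok.sum() < 3:
            return float("nan")
        coef = np.polyfit(np.log(boxes[ok]), np.log(fs[ok]), 1)
        return float(coef[0])

    alpha1 = slope(*scale_ranges[0])
    alpha2 = slope(*scale_ranges[1])
    return alpha1, alpha2


def device_hrv(sv, lf: float, hf: float, k: float = 0.1,
               conventional_ratio: bool = False,
               normalize_by_sv: bool = False) -> DeviceHRVFeatures:
    """Device-style HRV combining respiration depth with band powers.

    R-depth is the mean absolute residual of the stroke-volume series after
    exponential low-pass smoothing with constant ``k`` (optionally
    normalized by the mean |SV|); it is multiplied by HF/LF band power (the
    printed form) or LF/HF with ``conventional_ratio=True``.
    """
    sv = np.asarray(sv, dtype=float)
    if sv.size == 0:
        raise InsufficientData("empty stroke-volume window")
    if lf <= 0:
        raise InsufficientData("LF power must be positive for the HRV ratio")
    resid = np.abs(sv - lowpass_smooth(sv, k))
    rdepth = float(np.mean(resid))
    if normalize_by_sv:
        denom = float(np.mean(np.abs(sv)))
        rdepth = rdepth / denom if denom > 0 else np.nan
    ratio = (lf / hf) if conventional_ratio else (hf / lf)
    return DeviceHRVFeatures(rdepth=rdepth, hrv_rdepth=float(ratio * rdepth))
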