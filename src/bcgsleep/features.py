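"""Per-epoch 62-dimensional feature assembly.

Each 30-s epoch gets one row: 43 BCG-side features computed over the causal
5-min sliding window ending at the epoch (HRV time/frequency/nonlinear,
device R-depth HRV, vitals statistics, CPC band powers) and 19 audio
features computed on the epoch's own 30 s.  Missing data (too few valid
beats, absent audio stream) is represented explicitly in a validity mask
and imputed only at model-input time — never silently zero-filled.

The exact 62-item enumeration is fixed by the versioned feature dictionary
exported next to every matrix, so the dimensionality is reproducible by
construction.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from bcgsleep import audio as aud
from bcgsleep import cpc as cpcmod
from bcgsleep import hrv
from bcgsleep.preprocessing import WindowSpec, clean_beats, sliding_windows
from bcgsleep.signal_io import EPOCH_S, Session

RENYI_ORDERS = (0.25, 2.0, 5.0)

_BCG_FEATURES = [
    # time domain
    ("jj_mean", "ms", "hrv"), ("jj_sdnn", "ms", "hrv"), ("jj_rmssd", "ms", "hrv"),
    ("jj_pnn50", "fraction", "hrv"), ("jj_cv", "1", "hrv"),
    # frequency domain
    ("hrv_lf", "ms^2", "hrv"), ("hrv_hf", "ms^2", "hrv"),
    ("hrv_lf_hf", "1", "hrv"), ("hrv_total", "ms^2", "hrv"),
    ("hrv_lf_nu", "fraction", "hrv"), ("hrv_hf_nu", "fraction", "hrv"),
    # Poincaré geometry
    ("sd1", "ms", "hrv"), ("sd2", "ms", "hrv"), ("sd1_sd2", "1", "hrv"),
    # asymmetry
    ("porta", "%", "hrv"), ("guzik", "%", "hrv"), ("ehler", "1", "hrv"),
    ("phase_idx", "deg", "hrv"), ("area_idx", "%", "hrv"),
    # sequential trend analysis
    ("sta_d1", "ms", "hrv"), ("sta_d2", "ms", "hrv"),
    ("sta_d3", "ms", "hrv"), ("sta_d4", "ms", "hrv"),
    ("sta_occ1", "fraction", "hrv"), ("sta_occ4", "fraction", "hrv"),
    # entropies and fractal scaling
    ("sampen", "nat", "hrv"), ("apen", "nat", "hrv"),
    ("dfa_alpha1", "1", "hrv"), ("dfa_alpha2", "1", "hrv"),
    ("renyi_0p25", "bit", "hrv"), ("renyi_2", "bit", "hrv"),
    ("renyi_5", "bit", "hrv"),
    # device-style HRV
    ("rdepth", "device", "hrv"), ("hrv_rdepth", "device", "hrv"),
    ("sv_mean", "device", "hrv"),
    # vitals statistics
    ("bdr_mean", "breaths/min", "vitals"), ("bdr_sd", "breaths/min", "vitals"),
    ("hr_mean", "BPM", "vitals"), ("hr_sd", "BPM", "vitals"),
    # cardiopulmonary coupling
    ("cpc_lf", "power", "cpc"), ("cpc_hf", "power", "cpc"),
    ("cpc_ratio", "1", "cpc"), ("cpc_total", "power", "cpc"),
]

_AUDIO_FEATURES = [
    ("aud_cp", "s", "audio"), ("aud_ci", "1", "audio"), ("aud_cc", "1", "audio"),
    ("aud_if_mean", "Hz", "audio"), ("aud_if_sd", "Hz", "audio"),
    ("aud_if_median", "Hz", "audio"), ("aud_if_iqr", "Hz", "audio"),
    ("aud_e0_100", "power", "audio"), ("aud_e100_300", "power", "audio"),
    ("aud_e300_800", "power", "audio"), ("aud_e800_2000", "power", "audio"),
    ("aud_e2000_8000", "power", "audio"), ("aud_e_total", "power", "audio"),
    ("aud_spl_mean", "dBFS", "audio"), ("aud_spl_max", "dBFS", "audio"),
    ("aud_spl_sd", "dBFS", "audio"), ("aud_spl_rms", "dBFS", "audio"),
    ("aud_breath_count", "count", "audio"),
    ("aud_lowfreq_ratio", "fraction", "audio"),
]

FEATURE_NAMES: tuple[str, ...] = tuple(n for n, _, _ in _BCG_FEATURES + _AUDIO_FEATURES)
AUDIO_FEATURE_NAMES: tuple[str, ...] = tuple(n for n, _, _ in _AUDIO_FEATURES)


def feature_dictionary() -> list[dict]:
    """Machine-readable dictionary: name, unit and source module per column."""
    return [{"name": n, "unit": u, "source": s}
            for n, u, s in _BCG_FEATURES + _AUDIO_FEATURES]


@dataclasses.dataclass
class FeatureMatrix:
    """One row per 30-s epoch; explicit validity mask per cell."""

    subject_id: str
    session_id: str
    values: pd.DataFrame
    valid: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(FEATURE_NAMES):
            raise ValueError("columns must match the feature dictionary")
        if self.values.shape != self.valid.shape:
            raise ValueError("mask shape must match values")

    @property
    def n_epochs(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="epoch")
        side = Path(path).with_suffix(".dictionary.json")
        side.write_text(json.dumps(feature_dictionary(), indent=1))


def _hrv_row(jj: np.ndarray, onsets: np.ndarray, out: dict) -> None:
    try:
        t = hrv.time_domain(jj)
        out.update(jj_mean=t.mean_jj, jj_sdnn=t.sdnn, jj_rmssd=t.rmssd,
                   jj_pnn50=t.pnn50, jj_cv=t.cv_jj)
    except hrv.InsufficientData:
        pass
    try:
        f = hrv.freq_domain(onsets, jj)
        out.update(hrv_lf=f.lf_power, hrv_hf=f.hf_power, hrv_lf_hf=f.lf_hf_ratio,
                   hrv_total=f.total_power, hrv_lf_nu=f.lf_nu, hrv_hf_nu=f.hf_nu)
    except hrv.InsufficientData:
        pass
    try:
        sd1, sd2 = hrv.poincare_sd(jj)
        out.update(sd1=sd1, sd2=sd2, sd1_sd2=sd1 / sd2 if sd2 > 0 else np.nan)
    except hrv.InsufficientData:
        pass
    try:
        porta, guzik, ehler, phase, area = hrv.asymmetry_indices(jj)
        out.update(porta=porta, guzik=guzik, ehler=ehler,
                   phase_idx=phase, area_idx=area)
    except hrv.InsufficientData:
        pass
    try:
        sta = hrv.sta_features(jj)
        out.update(sta_d1=sta.q_dist[0], sta_d2=sta.q_dist[1],
                   sta_d3=sta.q_dist[2], sta_d4=sta.q_dist[3],
                   sta_occ1=sta.q_occupancy[0], sta_occ4=sta.q_occupancy[3])
    except hrv.InsufficientData:
        pass
    try:
        sampen, apen = hrv.sample_approx_entropy(jj)
        out.update(sampen=sampen if np.isfinite(sampen) else np.nan, apen=apen)
    except hrv.InsufficientData:
        pass
    try:
        a1, a2 = hrv.dfa(jj)
        out.update(dfa_alpha1=a1, dfa_alpha2=a2)
    except hrv.InsufficientData:
        pass
    try:
        ren = hrv.renyi_profile(jj, RENYI_ORDERS)
        out.update(renyi_0p25=ren[0.25], renyi_2=ren[2.0], renyi_5=ren[5.0])
    except hrv.InsufficientData:
        pass


def _audio_row(segment, out: dict) -> None:
    try:
        stats = aud.acoustic_stats(segment)
    except ValueError:
        return
    out.update(aud_if_mean=stats.instfreq_mean, aud_if_sd=stats.instfreq_sd,
               aud_if_median=stats.instfreq_median, aud_if_iqr=stats.instfreq_iqr,
               aud_e0_100=stats.band_energies[0], aud_e100_300=stats.band_energies[1],
               aud_e300_800=stats.band_energies[2], aud_e800_2000=stats.band_energies[3],
               aud_e2000_8000=stats.band_energies[4], aud_e_total=stats.total_energy,
               aud_spl_mean=stats.spl_mean, aud_spl_max=stats.spl_max,
               aud_spl_sd=stats.spl_sd, aud_spl_rms=stats.spl_rms)
    low = stats.band_energies[0] + stats.band_energies[1]
    out["aud_lowfreq_ratio"] = low / stats.total_energy if stats.total_energy > 0 else np.nan
    resp = aud.segment_respiration_features(segment)
    if resp.detected:
        out.update(aud_cp=resp.cp, aud_ci=resp.ci, aud_cc=resp.cc,
                   aud_breath_count=EPOCH_S / resp.cp if resp.cp > 0 else np.nan)
    else:
        out["aud_breath_count"] = 0.0


def assemble(session: Session, window_spec: WindowSpec = WindowSpec(),
             smoothing_k: float = 0.1) -> FeatureMatrix:
    """Build the per-epoch feature matrix for one session.

    Deterministic in (session, configs); rows equal the session's epoch
    count; audio columns stay masked-missing when the stream is absent.
    """
    beats = clean_beats(session.beat_series)
    windows = sliding_windows(session, window_spec)
    cpc_feats = None
    try:
        cpc_feats = cpcmod.cpc_series(session)
    except ValueError:
        pass

    rows = []
    for w in windows:
        out: dict = {name: np.nan for name in FEATURE_NAMES}
        seg = beats.slice(w.start_s, w.end_s)
        jj = seg.intervals
        _hrv_row(jj, seg.onset_times, out)

        vit = session.vitals.slice(w.start_s, w.end_s)
        if len(vit):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out.update(bdr_mean=np.nanmean(vit.bdr), bdr_sd=np.nanstd(vit.bdr),
                           hr_mean=np.nanmean(vit.hr), hr_sd=np.nanstd(vit.hr),
                           sv_mean=np.nanmean(vit.sv))
            lf, hf = out["hrv_lf"], out["hrv_hf"]
            if np.isfinite(lf) and lf > 0 and np.isfinite(hf):
                try:
                    dev = hrv.device_hrv(vit.sv[np.isfinite(vit.sv)], lf, hf,
                                         k=smoothing_k)
                    out.update(rdepth=dev.rdepth, hrv_rdepth=dev.hrv_rdepth)
                except hrv.InsufficientData:
                    pass

        if cpc_feats is not None and w.epoch_index < len(cpc_feats):
            c = cpc_feats[w.epoch_index]
            out.update(cpc_lf=c.lf_power, cpc_hf=c.hf_power,
                       cpc_ratio=c.lf_hf_ratio, cpc_total=c.total_power)

        if session.audio is not None:
            t0 = w.epoch_index * EPOCH_S
            segment = session.audio.segment(t0, t0 + EPOCH_S)
            if segment.samples.size >= aud.FRAME_LEN:
                _audio_row(segment, out)
        rows.append(out)

    values = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    valid = values.notna()
    return FeatureMatrix(session.subject_id, session.session_id, values, valid)


@dataclasses.dataclass
class Normalizer:
    """Column z-scoring with training-fold statistics only."""

    mean: pd.Series
    std: pd.Series

    @classmethod
    def fit(cls, matrices: Sequence[FeatureMatrix]) -> "Normalizer":
        stacked = pd.concat([m.values for m in matrices], ignore_index=True)
        mean = stacked.mean()
        std = stacked.std(ddof=0)
        degenerate = std[(std == 0) | std.isna()].index
        if len(degenerate):
            warnings.warn(
                f"zero-variance columns left unscaled: {list(degenerate)}",
                stacklevel=2)
        std = std.replace(0.0, 1.0).fillna(1.0)
        mean = mean.fillna(0.0)
        return cls(mean, std)

    def apply(self, matrix: FeatureMatrix) -> FeatureMatrix:
        values = (matrix.values - self.mean) / self.std
        return FeatureMatrix(matrix.subject_id, matrix.session_id,
                             values, matrix.valid.copy())


def normalize(train: Sequence[FeatureMatrix],
              apply_to: Sequence[FeatureMatrix]
              ) -> tuple[list[FeatureMatrix], Normalizer]:
    """Z-score ``apply_to`` with statistics fit on ``train`` only."""
    norm = Normalizer.fit(train)
    return [norm.apply(m) for m in apply_to], norm


def impute(matrix: FeatureMatrix, policy: str = "carry-forward") -> FeatureMatrix:
    """Fill masked cells (mask preserved for audit).

    carry-forward: previous epoch's value, column median for leading holes;
    column-median: per-column median; none: unchanged.
    """
    if policy == "none":
        return matrix
    values = matrix.values.copy()
    if policy == "carry-forward":
        values = values.ffill()
        values = values.fillna(values.median())
    elif policy == "column-median":
        values = values.fillna(values.median())
    else:
        raise ValueError(f"unknown imputation policy {policy!r}")
    values = values.fillna(0.0)  # columns missing in every epoch (e.g. no audio)
    return FeatureMatrix(matrix.subject_id, matrix.session_id, values,
                         matrix.valid.copy())
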