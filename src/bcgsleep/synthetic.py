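"""Synthetic sleep-session generator.

Emulates the signal structure the pipeline consumes, with no claim of
physiological fidelity: a first-order Markov hypnogram at 30-s pitch;
stage-conditioned JJ intervals carrying a 0.09 Hz low-frequency oscillation
and a respiration-frequency high-frequency (RSA-like) component whose
amplitude follows the stage's coupling gain; 1 Hz vitals whose respiration
rate and stroke volume share that respiratory oscillation (this shared
component is what makes cardiopulmonary coupling informative); sample
dropouts; and bedside audio with per-breath envelopes over band-limited
noise plus optional low-frequency snore bursts.

Stage parameters default to well-separated, physiologically plausible
values (wake fast and erratic, N3 slow with strong vagal respiratory
coupling, REM fast with sympathetic LF dominance).  Everything is a pure
function of (config, seed).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import signal as sps

from bcgsleep.signal_io import (
    EPOCH_S,
    AudioRecording,
    BeatIntervalSeries,
    Hypnogram,
    Session,
    STAGES,
    VitalsSeries,
)

LF_FREQ_HZ = 0.09  # inside the 0.04-0.15 Hz LF analysis band


@dataclasses.dataclass
class StageParams:
    """Cardiorespiratory character of one sleep stage."""

    hr_bpm: float          # mean heart rate
    lf_amp_ms: float       # 0.09 Hz beat-interval oscillation amplitude
    hf_amp_ms: float       # respiration-frequency oscillation amplitude
    resp_bpm: float        # respiration rate, breaths/min
    coupling_gain: float   # scales the shared respiratory component
    jitter_ms: float       # white beat-to-beat noise SD
    breath_amp: float      # audio breath-envelope amplitude
    snore_prob: float      # probability a breath carries a snore burst


DEFAULT_STAGE_PARAMS: dict[str, StageParams] = {
    "W":   StageParams(70.0, 35.0, 15.0, 16.0, 0.5, 25.0, 0.06, 0.00),
    "N1":  StageParams(64.0, 30.0, 25.0, 15.0, 0.8, 12.0, 0.08, 0.02),
    "N2":  StageParams(60.0, 20.0, 35.0, 14.0, 1.2, 8.0, 0.10, 0.10),
    "N3":  StageParams(55.0, 10.0, 45.0, 12.0, 1.5, 5.0, 0.12, 0.15),
    "REM": StageParams(66.0, 40.0, 12.0, 17.0, 0.4, 15.0, 0.07, 0.03),
}

#: 30-s transition matrix, rows/cols ordered as STAGES; tuned so wake bouts
#: flank the session (it starts in W) and N2 dominates sleep time.
DEFAULT_TRANSITIONS = np.array([
    # W      N1     N2     N3     REM
    [0.850, 0.120, 0.020, 0.000, 0.010],   # W
    [0.040, 0.700, 0.240, 0.000, 0.020],   # N1
    [0.010, 0.020, 0.890, 0.060, 0.020],   # N2
    [0.005, 0.005, 0.080, 0.900, 0.010],   # N3
    [0.020, 0.030, 0.060, 0.000, 0.890],   # REM
])


@dataclasses.dataclass
class SyntheticSessionConfig:
    seed: int = 0
    duration_s: float = 10800.0          # ~3 h, about 360 epochs
    transitions: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    stage_params: dict[str, StageParams] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_STAGE_PARAMS))
    dropout_rate: float = 0.01           # fraction of 1 Hz vitals samples lost
    sv_base: float = 1000.0              # stroke-volume baseline, device units
    sv_resp_mod: float = 0.25            # fractional SV respiratory modulation
    audio_rate: float = 8000.0           # Hz (features live below 4 kHz)
    audio_noise_floor: float = 0.005     # stationary background amplitude
    snore_amp: float = 0.25

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.transitions.shape != (5, 5):
            raise ValueError("transition matrix must be 5x5")
        if not np.allclose(self.transitions.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.transitions < 0):
            raise ValueError("transition probabilities must be non-negative")
        if self.duration_s < 600:
            raise ValueError("duration must be at least 600 s")
        for name, p in self.stage_params.items():
            if min(p.hr_bpm, p.resp_bpm) <= 0:
                raise ValueError(f"stage {name}: rates must be positive")
            if 60000.0 / p.hr_bpm <= p.lf_amp_ms + p.hf_amp_ms * p.coupling_gain:
                raise ValueError(f"stage {name}: oscillation amplitudes would "
                                 "produce non-positive JJ intervals")


@dataclasses.dataclass
class GroundTruth:
    hypnogram: Hypnogram
    stage_params: dict[str, StageParams]


def sample_hypnogram(cfg: SyntheticSessionConfig,
                     rng: Optional[np.random.Generator] = None) -> Hypnogram:
    """First-order Markov stage sequence at 30-s pitch, starting in W."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = int(cfg.duration_s // EPOCH_S)
    stages = []
    state = 0  # W
    for _ in range(n):
        stages.append(STAGES[state])
        state = rng.choice(5, p=cfg.transitions[state])
    return Hypnogram(tuple(stages))


def stationary_distribution(transitions: np.ndarray) -> np.ndarray:
    """Left eigenvector of the transition matrix at eigenvalue 1."""
    w, v = np.linalg.eig(transitions.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    return pi / pi.sum()


def _stage_of_time(hyp: Hypnogram) -> callable:
    stages = hyp.stages

    def at(t: float) -> str:
        k = min(int(t // EPOCH_S), len(stages) - 1)
        return stages[k]
    return at


def synth_cardiac(hyp: Hypnogram, cfg: SyntheticSessionConfig,
                  rng: Optional[np.random.Generator] = None
                  ) -> tuple[BeatIntervalSeries, VitalsSeries]:
    """Stage-conditioned beats and 1 Hz vitals sharing the respiratory
    oscillation.

    JJ_n = 60000/HR(stage) + A_LF sin(2 pi 0.09 t_n + phi1)
         + gain * A_HF sin(2 pi f_resp t_n + phi2) + noise, with beat onsets
    accumulating from the intervals.  The respiration-rate series and the
    stroke-volume amplitude are modulated at the same f_resp and phase, so
    tachogram-respiration coherence at f_resp reflects the coupling gain.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    duration = len(hyp) * EPOCH_S
    stage_at = _stage_of_time(hyp)
    phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)

    times, intervals = [], []
    t = 0.0
    while t < duration:
        p = cfg.stage_params[stage_at(t)]
        f_resp = p.resp_bpm / 60.0
        jj = (60000.0 / p.hr_bpm
              + p.lf_amp_ms * np.sin(2 * np.pi * LF_FREQ_HZ * t + phi1)
              + p.coupling_gain * p.hf_amp_ms
              * np.sin(2 * np.pi * f_resp * t + phi2)
              + rng.normal(0.0, p.jitter_ms))
        jj = max(jj, 250.0)
        t += jj / 1000.0
        if t >= duration:
            break
        times.append(t)
        intervals.append(jj)
    beats = BeatIntervalSeries(np.array(times), np.array(intervals))

    tv = np.arange(0.0, duration)
    hr = np.empty_like(tv)
    bdr = np.empty_like(tv)
    sv = np.empty_like(tv)
    for i, tt in enumerate(tv):
        p = cfg.stage_params[stage_at(tt)]
        f_resp = p.resp_bpm / 60.0
        resp_osc = np.sin(2 * np.pi * f_resp * tt + phi2)
        hr[i] = p.hr_bpm + rng.normal(0.0, 0.8)
        bdr[i] = (p.resp_bpm + 1.5 * resp_osc + rng.normal(0.0, 0.3))
        sv[i] = cfg.sv_base * (1.0 + cfg.sv_resp_mod * resp_osc) \
            + rng.normal(0.0, cfg.sv_base * 0.02)
    hr = np.maximum(hr, 1.0)
    bdr = np.maximum(bdr, 1.0)
    sv = np.maximum(sv, 0.0)

    if cfg.dropout_rate > 0:
        keep = rng.random(tv.size) >= cfg.dropout_rate
        keep[0] = keep[-1] = True  # preserve the support
        tv, hr, bdr, sv = tv[keep], hr[keep], bdr[keep], sv[keep]
    vitals = VitalsSeries(tv, hr, bdr, sv)
    return beats, vitals


def synth_audio(hyp: Hypnogram, cfg: SyntheticSessionConfig,
                rng: Optional[np.random.Generator] = None) -> AudioRecording:
    """Breathing-sound audio: per-breath raised-cosine envelopes over
    band-limited noise, optional 60-300 Hz snore bursts, stationary noise
    floor."""
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    fs = cfg.audio_rate
    duration = len(hyp) * EPOCH_S
    n = int(duration * fs)
    out = cfg.audio_noise_floor * rng.standard_normal(n)
    stage_at = _stage_of_time(hyp)

    nyq = fs / 2.0
    b_breath, a_breath = sps.butter(2, [300.0 / nyq, min(1800.0, nyq * 0.9) / nyq],
                                    btype="band")
    b_snore, a_snore = sps.butter(2, [60.0 / nyq, 300.0 / nyq], btype="band")

    t = 0.0
    while t < duration:
        p = cfg.stage_params[stage_at(t)]
        period = 60.0 / p.resp_bpm
        breath_len = 0.4 * period  # audible inhale/exhale portion
        i0 = int(t * fs)
        i1 = min(int((t + breath_len) * fs), n)
        if i1 - i0 > 8 and p.breath_amp > 0:
            m = i1 - i0
            env = 0.5 * (1 - np.cos(2 * np.pi * np.arange(m) / m))
            carrier = sps.lfilter(b_breath, a_breath, rng.standard_normal(m))
            burst = p.breath_amp * env * carrier
            if rng.random() < p.snore_prob:
                snore = sps.lfilter(b_snore, a_snore, rng.standard_normal(m))
                burst = burst + cfg.snore_amp * env * snore
            out[i0:i1] += burst
        t += period
    peak = np.max(np.abs(out))
    if peak > 1.0:
        out /= peak
    return AudioRecording(out, fs)


def synthesize_session(cfg: SyntheticSessionConfig,
                       subject_id: str = "S0", session_id: str = "R0",
                       audio: bool = True) -> tuple[Session, GroundTruth]:
    """Full session (beats, vitals, optional audio) plus ground truth."""
    rng = np.random.default_rng(cfg.seed)
    hyp = sample_hypnogram(cfg, rng)
    beats, vitals = synth_cardiac(hyp, cfg, rng)
    rec = synth_audio(hyp, cfg, rng) if audio else None
    session = Session(subject_id, session_id, beats, vitals, rec, hyp)
    return session, GroundTruth(hyp, dict(cfg.stage_params))


def _jitter_params(base: dict[str, StageParams],
                   rng: np.random.Generator) -> dict[str, StageParams]:
    """Subject effects: correlated shifts of rates and amplitudes."""
    hr_shift = rng.normal(0.0, 2.5)
    resp_shift = rng.normal(0.0, 1.0)
    amp_scale = rng.lognormal(0.0, 0.1)
    snore_scale = rng.lognormal(0.0, 0.5)
    out = {}
    for stage, p in base.items():
        out[stage] = StageParams(
            hr_bpm=p.hr_bpm + hr_shift,
            lf_amp_ms=p.lf_amp_ms * amp_scale,
            hf_amp_ms=p.hf_amp_ms * amp_scale,
            resp_bpm=max(p.resp_bpm + resp_shift, 6.0),
            coupling_gain=p.coupling_gain,
            jitter_ms=p.jitter_ms,
            breath_amp=p.breath_amp,
            snore_prob=min(p.snore_prob * snore_scale, 0.8),
        )
    return out


def make_cohort(n_subjects: int = 9, sessions_each: int = 3,
                base_seed: int = 0,
                base_config: Optional[SyntheticSessionConfig] = None,
                audio: bool = True
                ) -> tuple[list[Session], list[GroundTruth]]:
    """Cohort of subjects with per-subject parameter jitter.

    Deterministic per (base_seed, subject, session); subjects differ
    through correlated shifts of their stage parameters.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    base = base_config or SyntheticSessionConfig()
    sessions, truths = [], []
    for s in range(n_subjects):
        subj_rng = np.random.default_rng([base_seed, s])
        params = _jitter_params(base.stage_params, subj_rng)
        for r in range(sessions_each):
            seed = int(np.random.default_rng([base_seed, s, r]).integers(2 ** 31))
            cfg = dataclasses.replace(base, seed=seed, stage_params=params)
            sess, truth = synthesize_session(
                cfg, subject_id=f"S{s}", session_id=f"R{r}", audio=audio)
            sessions.append(sess)
            truths.append(truth)
    return sessions, truths
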