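"""Stream conditioning: exponential smoothing, gap filling, artifact
masking, sliding-window segmentation and uniform resampling.

The exponential low-pass is the single-pole recurrence
``y(t) = (1-k)*y(t-1) + k*x(t)`` with filter constant ``k`` in (0, 1];
``k = 1`` is the identity.  HRV analysis windows are 5 min long, stepped by
30 s so every epoch gets exactly one (possibly left-truncated) window.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from bcgsleep.signal_io import (
    EPOCH_S,
    BeatIntervalSeries,
    Session,
    VitalsSeries,
)

REASON_OK = 0
REASON_DROPOUT = 1
REASON_RANGE = 2
REASON_JUMP = 3

# artifact screen: valid JJ in [300, 2000] ms spans 30-200 BPM; a >30% jump
# versus the previous valid beat flags motion/ectopy suspects
DEFAULT_JJ_LO_MS = 300.0
DEFAULT_JJ_HI_MS = 2000.0
DEFAULT_JUMP_FRAC = 0.3


@dataclasses.dataclass
class SmoothingConfig:
    k: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.k <= 1.0:
            raise ValueError("filter constant k must be in (0, 1]")


@dataclasses.dataclass
class WindowSpec:
    """Sliding analysis window: length 300 s stepped by 30 s by default."""

    length_s: float = 300.0
    step_s: float = EPOCH_S

    def __post_init__(self) -> None:
        if self.length_s <= 0 or self.step_s <= 0:
            raise ValueError("window length and step must be positive")
        if (self.length_s / self.step_s) % 1 != 0:
            raise ValueError("step must divide window length")


@dataclasses.dataclass
class ArtifactMask:
    """Per-sample validity with a reason code per invalid sample."""

    valid: np.ndarray
    reason: np.ndarray

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        self.reason = np.asarray(self.reason, dtype=int)
        if self.valid.shape != self.reason.shape:
            raise ValueError("valid and reason must have equal length")


def lowpass_smooth(x, k: float, y0: Optional[float] = None) -> np.ndarray:
    """Single-pole exponential low-pass, y(t) = (1-k)y(t-1) + k x(t).

    ``y0`` seeds the recurrence (y(-1)); defaults to the first sample, which
    makes a constant input an exact fixed point.
    """
    if not 0.0 < k <= 1.0:
        raise ValueError("filter constant k must be in (0, 1]")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input samples must be finite")
    if x.size == 0:
        return x.copy()
    y = np.empty_like(x)
    prev = float(x[0]) if y0 is None else float(y0)
    for i, xi in enumerate(x):
        prev = (1.0 - k) * prev + k * xi
        y[i] = prev
    return y


def fill_gaps(v: VitalsSeries, max_gap_s: float = 30.0
              ) -> tuple[VitalsSeries, ArtifactMask]:
    """Rebuild the 1 Hz grid; linearly interpolate gaps up to ``max_gap_s``.

    Returns the gap-filled series and a mask over the full grid: originally
    present samples are valid, interpolated samples valid with reason
    ``REASON_DROPOUT`` recorded, gaps beyond the limit invalid (filled with
    NaN, never fabricated).
    """
    if len(v) == 0:
        return v, ArtifactMask(np.zeros(0, bool), np.zeros(0, int))
    t0, t1 = v.t[0], v.t[-1]
    grid = np.arange(np.round(t0), np.round(t1) + 1.0)
    present = np.isin(grid, np.round(v.t))
    valid = np.ones(grid.size, dtype=bool)
    reason = np.zeros(grid.size, dtype=int)

    def interp(col: np.ndarray) -> np.ndarray:
        return np.interp(grid, v.t, col)

    hr, bdr, sv = interp(v.hr), interp(v.bdr), interp(v.sv)
    hrv = interp(v.hrv_device) if v.hrv_device is not None else None

    # walk gaps between present samples; mark interpolated vs invalid
    missing_idx = np.flatnonzero(~present)
    if missing_idx.size:
        splits = np.split(missing_idx, np.flatnonzero(np.diff(missing_idx) > 1) + 1)
        for run in splits:
            gap_len = run.size
            if gap_len <= max_gap_s:
                reason[run] = REASON_DROPOUT
            else:
                valid[run] = False
                reason[run] = REASON_DROPOUT
                for col in (hr, bdr, sv) + ((hrv,) if hrv is not None else ()):
                    col[run] = np.nan
    filled = VitalsSeries(grid, hr, bdr, sv, hrv)
    return filled, ArtifactMask(valid, reason)


def mask_artifacts(b: BeatIntervalSeries,
                   lo_ms: float = DEFAULT_JJ_LO_MS,
                   hi_ms: float = DEFAULT_JJ_HI_MS,
                   jump_frac: float = DEFAULT_JUMP_FRAC) -> ArtifactMask:
    """Flag physiologically implausible beats and large jumps.

    Beats outside [lo_ms, hi_ms] are range violations; a beat differing from
    the previous *valid* beat by more than ``jump_frac`` (relative) is a
    movement/ectopy suspect.
    """
    if lo_ms <= 0 or hi_ms <= 0 or lo_ms >= hi_ms:
        raise ValueError("need 0 < lo_ms < hi_ms")
    jj = b.intervals
    valid = np.ones(jj.size, dtype=bool)
    reason = np.zeros(jj.size, dtype=int)
    prev_valid: Optional[float] = None
    for i, x in enumerate(jj):
        if not lo_ms <= x <= hi_ms:
            valid[i] = False
            reason[i] = REASON_RANGE
            continue
        if prev_valid is not None and abs(x - prev_valid) / prev_valid > jump_frac:
            valid[i] = False
            reason[i] = REASON_JUMP
            continue
        prev_valid = x
    return ArtifactMask(valid, reason)


def clean_beats(b: BeatIntervalSeries, **kwargs) -> BeatIntervalSeries:
    """Drop masked beats (removal, not interpolation, so variability metrics
    are not distorted by fabricated intervals)."""
    mask = mask_artifacts(b, **kwargs)
    return BeatIntervalSeries(b.onset_times[mask.valid], b.intervals[mask.valid])


@dataclasses.dataclass
class AnalysisWindow:
    """Per-epoch analysis window [start_s, end_s); partial when truncated at
    the session start (the first length/step - 1 epochs)."""

    epoch_index: int
    start_s: float
    end_s: float
    partial: bool


def sliding_windows(session: Session, spec: WindowSpec = WindowSpec()
                    ) -> list[AnalysisWindow]:
    """One causal window per 30-s epoch: the ``length_s`` seconds ending at
    that epoch's end, left-truncated (and flagged partial) near the start."""
    n = session.n_epochs
    if n < 1:
        raise ValueError("session shorter than one epoch")
    windows = []
    for k in range(n):
        end = (k + 1) * EPOCH_S
        start = end - spec.length_s
        partial = start < 0
        windows.append(AnalysisWindow(k, max(start, 0.0), end, partial))
    return windows


def resample_uniform(t, x, target_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline resampling onto a uniform grid spanning the support.

    Needs >= 4 points; the interpolant passes through the original samples.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size < 4:
        raise ValueError("cubic-spline resampling needs at least 4 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing")
    spline = CubicSpline(t, x)
    n = int(np.floor((t[-1] - t[0]) * target_hz)) + 1
    grid = t[0] + np.arange(n) / target_hz
    return grid, spline(grid)
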