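"""Session I/O: beat intervals, 1 Hz vitals, audio and hypnograms.

All streams are mapped onto one session clock (seconds from session start)
and segmented on a common 30-s epoch grid.  Epoch windows are half-open
``[k*30, (k+1)*30)`` with 0-based indices.

File dialects: CSV with a header row for vitals (``t,hr,bdr,sv,hrv``), beat
intervals (``t,jj_ms``) and hypnograms (``epoch,stage``); WAV (PCM 16/24-bit
or float, mono) for audio; a YAML/JSON manifest names the files and the
per-stream synchronization offsets.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

EPOCH_S = 30.0

#: 5-class sleep-stage alphabet (AASM): wake, three non-REM depths, REM.
STAGES = ("W", "N1", "N2", "N3", "REM")
#: 3-class relabeling: non-REM depths merged.
STAGES_3CLASS = ("W", "NREM", "REM")


class ParseError(ValueError):
    """Malformed input row; message names the offending file and line."""


@dataclasses.dataclass
class BeatIntervalSeries:
    """Timestamped JJ (beat-to-beat) intervals.

    ``onset_times`` are seconds from session start, strictly increasing;
    ``intervals`` are the corresponding JJ intervals in milliseconds.
    """

    onset_times: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.onset_times.shape != self.intervals.shape:
            raise ValueError("onset_times and intervals must have equal length")
        if np.any(self.intervals <= 0):
            raise ValueError("JJ intervals must be positive")
        if self.onset_times.size > 1 and np.any(np.diff(self.onset_times) <= 0):
            raise ValueError("onset_times must be strictly increasing")

    def __len__(self) -> int:
        return self.onset_times.size

    def shifted(self, offset_s: float) -> "BeatIntervalSeries":
        return BeatIntervalSeries(self.onset_times - offset_s, self.intervals.copy())

    def slice(self, t0: float, t1: float) -> "BeatIntervalSeries":
        """Beats with onset in [t0, t1)."""
        m = (self.onset_times >= t0) & (self.onset_times < t1)
        return BeatIntervalSeries(self.onset_times[m], self.intervals[m])


@dataclasses.dataclass
class VitalsSeries:
    """1 Hz vitals: heart rate (BPM), respiration rate (breaths/min),
    stroke-volume amplitude (device units) and optional device HRV (ms)."""

    t: np.ndarray
    hr: np.ndarray
    bdr: np.ndarray
    sv: np.ndarray
    hrv_device: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("hr", "bdr", "sv"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise ValueError(f"{name} length must match t")
            setattr(self, name, arr)
        if self.hrv_device is not None:
            self.hrv_device = np.asarray(self.hrv_device, dtype=float)

    def __len__(self) -> int:
        return self.t.size

    def shifted(self, offset_s: float) -> "VitalsSeries":
        hrv = None if self.hrv_device is None else self.hrv_device.copy()
        return VitalsSeries(self.t - offset_s, self.hr.copy(), self.bdr.copy(),
                            self.sv.copy(), hrv)

    def slice(self, t0: float, t1: float) -> "VitalsSeries":
        m = (self.t >= t0) & (self.t < t1)
        hrv = None if self.hrv_device is None else self.hrv_device[m]
        return VitalsSeries(self.t[m], self.hr[m], self.bdr[m], self.sv[m], hrv)


@dataclasses.dataclass
class AudioRecording:
    """Mono PCM audio, float samples nominally in [-1, 1]."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("audio must be mono (1-D)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def segment(self, t0: float, t1: float) -> "AudioRecording":
        i0 = max(0, int(round(t0 * self.sample_rate)))
        i1 = min(self.samples.size, int(round(t1 * self.sample_rate)))
        return AudioRecording(self.samples[i0:i1], self.sample_rate)


@dataclasses.dataclass
class Hypnogram:
    """Per-epoch sleep-stage labels with contiguous 0-based epoch indices."""

    stages: tuple

    def __post_init__(self) -> None:
        stages = tuple(self.stages)
        alphabet = set(STAGES) | set(STAGES_3CLASS)
        for s in stages:
            if s not in alphabet:
                raise ValueError(f"unknown sleep stage {s!r}")
        self.stages = stages

    def __len__(self) -> int:
        return len(self.stages)

    def __eq__(self, other) -> bool:
        return isinstance(other, Hypnogram) and self.stages == other.stages

    def as_array(self) -> np.ndarray:
        return np.asarray(self.stages, dtype=object)


@dataclasses.dataclass
class Session:
    """All streams of one recording on a shared session clock."""

    subject_id: str
    session_id: str
    beat_series: BeatIntervalSeries
    vitals: VitalsSeries
    audio: Optional[AudioRecording] = None
    hypnogram: Optional[Hypnogram] = None

    @property
    def duration_s(self) -> float:
        """Duration of the mandatory streams, truncated to whole epochs.

        The 1 Hz vitals grid defines coverage; the sparse beat events only
        truncate it when they end before the vitals' last whole epoch
        (beat coverage is rounded up to the epoch boundary, since a beat
        late in an epoch still covers it).
        """
        if not len(self.vitals):
            return 0.0
        dur = self.vitals.t[-1] + 1.0
        if len(self.beat_series):
            beats_end = np.ceil(self.beat_series.onset_times[-1] / EPOCH_S) \
                * EPOCH_S
            dur = min(dur, beats_end)
        return np.floor(dur / EPOCH_S) * EPOCH_S

    @property
    def n_epochs(self) -> int:
        return int(self.duration_s // EPOCH_S)


def epoch_grid(session: Session) -> list[tuple[float, float]]:
    """Half-open 30-s epoch windows ``[k*30, (k+1)*30)`` covering the session.

    The count is ``floor(duration / 30)``; raises if the session is shorter
    than one epoch.
    """
    n = session.n_epochs
    if n < 1:
        raise ValueError("session shorter than one 30-s epoch")
    return [(k * EPOCH_S, (k + 1) * EPOCH_S) for k in range(n)]


# ---------------------------------------------------------------------------
# readers / writers


def read_beats(path) -> BeatIntervalSeries:
    """Read a beat-interval CSV (``t,jj_ms``). Raises ParseError naming the
    first offending line on malformed or invariant-violating rows."""
    t, jj = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("t"):
            raise ParseError(f"{path}: line 1: expected header 't,jj_ms'")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                ti, ji = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {lineno}: {line!r}") from exc
            if ji <= 0:
                raise ParseError(
                    f"{path}: line {lineno}: non-positive JJ interval {ji}")
            t.append(ti)
            jj.append(ji)
    return BeatIntervalSeries(np.array(t), np.array(jj))


def write_beats(series: BeatIntervalSeries, path) -> None:
    df = pd.DataFrame({"t": series.onset_times, "jj_ms": series.intervals})
    df.to_csv(path, index=False)


def read_vitals(path) -> VitalsSeries:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"{path}: {exc}") from exc
    required = {"t", "hr", "bdr", "sv"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    hrv = df["hrv"].to_numpy() if "hrv" in df.columns else None
    return VitalsSeries(df["t"].to_numpy(), df["hr"].to_numpy(),
                        df["bdr"].to_numpy(), df["sv"].to_numpy(), hrv)


def write_vitals(v: VitalsSeries, path) -> None:
    data = {"t": v.t, "hr": v.hr, "bdr": v.bdr, "sv": v.sv}
    if v.hrv_device is not None:
        data["hrv"] = v.hrv_device
    pd.DataFrame(data).to_csv(path, index=False)


def read_hypnogram(path) -> Hypnogram:
    stages = []
    with open(path) as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                idx, stage = int(parts[0]), parts[1].strip()
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {lineno}: {line!r}") from exc
            if idx != len(stages):
                raise ParseError(f"{path}: line {lineno}: epoch indices not contiguous")
            stages.append(stage)
    return Hypnogram(tuple(stages))


def write_hypnogram(h: Hypnogram, path) -> None:
    """Write ``epoch,stage`` CSV; round-trips exactly via read_hypnogram."""
    with open(path, "w") as fh:
        fh.write("epoch,stage\n")
        for i, s in enumerate(h.stages):
            fh.write(f"{i},{s}\n")


def read_audio(path) -> AudioRecording:
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ParseError(f"{path}: only mono WAV is supported, got {data.ndim} channels")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(float)
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 128.0
    else:
        raise ParseError(f"{path}: unsupported WAV sample format {data.dtype}")
    return AudioRecording(samples, float(rate))


def write_audio(a: AudioRecording, path) -> None:
    pcm = np.clip(a.samples, -1.0, 1.0)
    wavfile.write(path, int(a.sample_rate),
                  np.round(pcm * 32767).astype(np.int16))


def read_manifest(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def read_session(manifest_path) -> Session:
    """Assemble a Session from a manifest naming files and per-stream offsets.

    Manifest keys: ``subject_id``, ``session_id``, ``beats``, ``vitals``,
    optional ``audio`` and ``hypnogram`` paths, and an ``offsets`` mapping
    (seconds per stream).  An offset of +d means the stream's own clock runs
    d seconds ahead of the session clock, so its timestamps are shifted by
    -d onto the session clock.
    """
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    offsets = manifest.get("offsets", {}) or {}
    for v in offsets.values():
        if not np.isfinite(v):
            raise ValueError("stream offsets must be finite")

    beats = read_beats(base / manifest["beats"]).shifted(offsets.get("beats", 0.0))
    vitals = read_vitals(base / manifest["vitals"]).shifted(offsets.get("vitals", 0.0))

    audio = None
    if manifest.get("audio"):
        audio = read_audio(base / manifest["audio"])
        off = offsets.get("audio", 0.0)
        if off:
            shift = int(round(off * audio.sample_rate))
            if shift > 0:
                audio = AudioRecording(audio.samples[shift:], audio.sample_rate)
            elif shift < 0:
                pad = np.zeros(-shift)
                audio = AudioRecording(np.concatenate([pad, audio.samples]),
                                       audio.sample_rate)

    hyp = None
    if manifest.get("hypnogram"):
        hyp = read_hypnogram(base / manifest["hypnogram"])

    session = Session(
        subject_id=str(manifest.get("subject_id", "S0")),
        session_id=str(manifest.get("session_id", "R0")),
        beat_series=beats,
        vitals=vitals,
        audio=audio,
        hypnogram=hyp,
    )
    if hyp is not None and len(hyp) > session.n_epochs:
        session.hypnogram = Hypnogram(hyp.stages[: session.n_epochs])
    return session


def write_session(session: Session, directory, audio: bool = True) -> Path:
    """Write all session artifacts plus a YAML manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_beats(session.beat_series, directory / "beats.csv")
    write_vitals(session.vitals, directory / "vitals.csv")
    manifest = {
        "subject_id": session.subject_id,
        "session_id": session.session_id,
        "beats": "beats.csv",
        "vitals": "vitals.csv",
        "offsets": {"beats": 0.0, "vitals": 0.0, "audio": 0.0},
    }
    if audio and session.audio is not None:
        write_audio(session.audio, directory / "audio.wav")
        manifest["audio"] = "audio.wav"
    if session.hypnogram is not None:
        write_hypnogram(session.hypnogram, directory / "hypnogram.csv")
        manifest["hypnogram"] = "hypnogram.csv"
    path = directory / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path
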