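"""Core containers shared by every stage of the pipeline.

Conventions: sample indices are 0-based; times are seconds from the start of
the record (``t0`` offsets a window cut from a longer record); rates are
breaths/min (bpm) for respiration and beats/min for heart rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RESP_BAND_BPM = (4.0, 60.0)  # plausible respiratory band
CARDIAC_BAND_BPM = (30.0, 220.0)  # plausible cardiac band


@dataclass
class Waveform:
    """Uniformly sampled physiological signal."""

    samples: np.ndarray
    fs: float
    signal_type: str  # "ecg" | "ppg" | "pressure"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size == 0:
            raise ValueError("waveform must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        self.signal_type = self.signal_type.lower()
        if self.signal_type not in ("ecg", "ppg", "pressure"):
            raise ValueError(f"unknown signal type {self.signal_type!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def slice(self, start_s: float, end_s: float) -> "Waveform":
        """Half-open time slice [start_s, end_s) in absolute seconds."""
        i0 = int(round((start_s - self.t0) * self.fs))
        i1 = int(round((end_s - self.t0) * self.fs))
        i0, i1 = max(i0, 0), min(i1, self.samples.size)
        return Waveform(self.samples[i0:i1], self.fs, self.signal_type,
                        t0=self.t0 + i0 / self.fs)


@dataclass
class BeatAnnotations:
    """Per-beat fiducial sample indices on a waveform.

    ``q_idx``/``s_idx`` are ECG-only and ``None`` for PPG. ``valid`` is False
    when detection found fewer than two beats (degenerate input).
    """

    peak_idx: np.ndarray  # R-wave or pulse-peak index per beat
    trough_idx: np.ndarray  # per-beat trough (before R / between pulses)
    q_idx: np.ndarray | None = None
    s_idx: np.ndarray | None = None
    valid: bool = True

    def __post_init__(self) -> None:
        self.peak_idx = np.asarray(self.peak_idx, dtype=int)
        self.trough_idx = np.asarray(self.trough_idx, dtype=int)
        if self.peak_idx.size >= 2 and np.any(np.diff(self.peak_idx) <= 0):
            raise ValueError("beat indices must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.peak_idx.size)


@dataclass
class FeatureSeries:
    """Beat-by-beat feature measurements at irregular (beat-aligned) times."""

    times: np.ndarray
    values: np.ndarray
    technique: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("feature times must be strictly increasing")


@dataclass
class RespiratorySignal:
    """Regularly sampled series dominated by respiratory modulation."""

    values: np.ndarray
    fs: float
    technique: str
    modulation_tag: str = "mixed"  # bw | am | fm | mixed
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    def slice(self, start_s: float, end_s: float) -> "RespiratorySignal":
        """Half-open time slice [start_s, end_s) in absolute seconds."""
        i0 = max(int(np.ceil((start_s - self.t0) * self.fs)), 0)
        i1 = min(int(np.ceil((end_s - self.t0) * self.fs)),
                 self.values.size)
        return RespiratorySignal(self.values[i0:i1], self.fs,
                                 self.technique, self.modulation_tag,
                                 t0=self.t0 + i0 / self.fs)


@dataclass
class RREstimate:
    """One RR value in bpm for one window, or an explicit no-output state."""

    rr: float | None
    window_id: str = ""
    technique_chain: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.rr is not None:
            lo, hi = RESP_BAND_BPM
            if not (lo <= self.rr <= hi):
                raise ValueError(f"rr={self.rr} outside [{lo}, {hi}] bpm")

    @property
    def has_output(self) -> bool:
        return self.rr is not None


NO_OUTPUT = None  # sentinel meaning "technique declined to emit an RR"
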