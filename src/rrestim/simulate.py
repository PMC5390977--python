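"""Respiration-modulated ECG/PPG beat trains with known ground truth.

A single analytic beat template (idealised ECG PQRST morphology, or a PPG
pulse with systolic peak and dicrotic shoulder) is replicated at the target
heart rate and the resulting train is modulated by one of the three
respiratory modulations:

* BW — a sinusoid at the respiratory frequency is added to the baseline;
* AM — the train is multiplied by ``1 + depth * sin(2*pi*f_resp*t)``;
* FM — successive beat-to-beat intervals are modulated sinusoidally around
  ``60/hr`` seconds with fractional amplitude ``depth``.

Beats are rendered by phase: each sample's value is the template evaluated at
its fractional position within the containing beat interval, so FM stretches
the whole beat (including QRS width and peak spacing) while AM and BW leave
beat timing untouched.  The verification sweep enumerates the standard grid:
for each modulation, 35 settings varying HR 30:5:200 at RR = 18 bpm, and 29
settings varying RR 4:2:60 at HR = 80 bpm, each rendered for both ECG and
PPG (192 settings, 384 waveforms).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from .core import Waveform

# Template bump positions as fractions of one beat: (centre, amplitude, width)
_ECG_BUMPS = (
    (0.14, 0.12, 0.025),   # P
    (0.275, -0.12, 0.008),  # Q
    (0.30, 1.20, 0.010),   # R
    (0.325, -0.22, 0.008),  # S
    (0.55, 0.28, 0.045),   # T
)
_PPG_BUMPS = (
    (0.35, 1.00, 0.10),    # systolic peak
    (0.65, 0.35, 0.08),    # dicrotic shoulder
)


@dataclass(frozen=True)
class BeatTemplate:
    """One canonical beat sampled over a nominal 1 s interval."""

    samples: np.ndarray
    fs: float
    signal_type: str

    @property
    def phase_grid(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.samples.size


@dataclass(frozen=True)
class SimulationConfig:
    signal_type: str  # "ecg" | "ppg"
    modulation: str  # "bw" | "am" | "fm"
    hr: float  # beats/min
    rr: float  # breaths/min
    duration: float = 210.0  # s
    fs: float = 500.0  # samples/s
    depth: float = 0.1  # modulation strength (fractional)
    phase: float = 0.0  # phase of the modulating sinusoid, radians
    sweep: int | None = None  # 1 = HR sweep, 2 = RR sweep (verification set)

    def __post_init__(self) -> None:
        if self.signal_type.lower() not in ("ecg", "ppg"):
            raise ValueError(f"unknown signal type {self.signal_type!r}")
        if not 30.0 <= self.hr <= 200.0:
            raise ValueError(f"hr={self.hr} outside [30, 200] beats/min")
        if not 4.0 <= self.rr <= 60.0:
            raise ValueError(f"rr={self.rr} outside [4, 60] bpm")
        if self.depth < 0:
            raise ValueError("modulation depth must be >= 0")
        if self.fs < 125:
            raise ValueError("sampling rate must be >= 125 Hz")
        if self.modulation.lower() not in ("bw", "am", "fm"):
            raise ValueError(f"unknown modulation {self.modulation!r}")


@dataclass(frozen=True)
class SimulatedSignal:
    waveform: Waveform
    config: SimulationConfig
    beat_onsets: np.ndarray  # seconds; ground-truth beat placement


def _bump_profile(phase: np.ndarray, bumps) -> np.ndarray:
    """Sum of periodically wrapped Gaussian bumps evaluated at phase."""
    out = np.zeros_like(phase)
    for centre, amp, width in bumps:
        d = (phase - centre + 0.5) % 1.0 - 0.5
        out += amp * np.exp(-0.5 * (d / width) ** 2)
    return out


def make_beat_template(signal_type: str, fs: float = 500.0) -> BeatTemplate:
    """Deterministic analytic beat template, unit peak amplitude.

    ECG: PQRST as a sum of localised Gaussian bumps, global maximum at the
    R-wave analogue. PPG: skewed pulse with systolic peak and dicrotic
    shoulder, baseline-shifted so its minimum is exactly 0.
    """
    st = signal_type.lower()
    n = int(round(fs))  # one nominal 1 s beat
    phase = np.arange(n) / n
    if st == "ecg":
        y = _bump_profile(phase, _ECG_BUMPS)
    elif st == "ppg":
        y = _bump_profile(phase, _PPG_BUMPS)
        y -= y.min()  # non-negative pulse
    else:
        raise ValueError(f"unknown signal type {signal_type!r}")
    y /= y.max()
    return BeatTemplate(samples=y, fs=fs, signal_type=st)


def _beat_onsets(config: SimulationConfig) -> np.ndarray:
    """Sequential beat onset times; FM modulates successive intervals."""
    t_mean = 60.0 / config.hr
    f_resp = config.rr / 60.0
    onsets = [0.0]
    while onsets[-1] < config.duration:
        t_k = onsets[-1]
        if config.modulation == "fm":
            interval = t_mean * (1.0 + config.depth
                                 * np.sin(2 * np.pi * f_resp * t_k
                                          + config.phase))
        else:
            interval = t_mean
        onsets.append(t_k + interval)
    return np.asarray(onsets)


def generate_modulated_train(config: SimulationConfig) -> SimulatedSignal:
    """Render one modulated beat train per the configuration."""
    template = make_beat_template(config.signal_type, config.fs)
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    onsets = _beat_onsets(config)

    # phase of each sample within its containing beat interval
    k = np.searchsorted(onsets, t, side="right") - 1
    k = np.clip(k, 0, onsets.size - 2)
    intervals = np.diff(onsets)
    phase = (t - onsets[k]) / intervals[k]
    y = np.interp(phase, template.phase_grid, template.samples,
                  period=1.0)

    f_resp = config.rr / 60.0
    mod = np.sin(2 * np.pi * f_resp * t + config.phase)
    if config.modulation == "bw":
        y = y + config.depth * mod
    elif config.modulation == "am":
        y = y * (1.0 + config.depth * mod)
    # fm already encoded in the onsets

    wf = Waveform(y, config.fs, config.signal_type)
    visible = onsets[onsets < config.duration]
    return SimulatedSignal(waveform=wf, config=config, beat_onsets=visible)


def verification_configs(signal_types: tuple = ("ecg", "ppg"),
                         depth: float = 0.1,
                         phase: float = 0.0) -> list[SimulationConfig]:
    """The full verification grid of simulation settings.

    For each modulation: sweep 1 holds RR = 18 bpm and varies HR over
    30:5:200 (35 settings); sweep 2 holds HR = 80 and varies RR over 4:2:60
    (29 settings). Each of the 192 (modulation, HR, RR) settings is emitted
    once per requested signal type.
    """
    configs = []
    for modulation in ("bw", "am", "fm"):
        for st in signal_types:
            for hr in range(30, 201, 5):
                configs.append(SimulationConfig(
                    st, modulation, hr=float(hr), rr=18.0,
                    depth=depth, phase=phase, sweep=1))
            for rr in range(4, 61, 2):
                configs.append(SimulationConfig(
                    st, modulation, hr=80.0, rr=float(rr),
                    depth=depth, phase=phase, sweep=2))
    return configs


def generate_verification_set(signal_types: tuple = ("ecg", "ppg"),
                              depth: float = 0.1,
                              phase: float = 0.0,
                              ) -> Iterator[SimulatedSignal]:
    """Lazily render every waveform of the verification sweep."""
    for config in verification_configs(signal_types, depth, phase):
        yield generate_modulated_train(config)


def with_random_phase(config: SimulationConfig,
                      rng: np.random.Generator) -> SimulationConfig:
    """Copy of ``config`` with the modulating sinusoid's phase randomised."""
    return replace(config, phase=float(rng.uniform(0, 2 * np.pi)))
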