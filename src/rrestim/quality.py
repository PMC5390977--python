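"""Signal-quality gating and reference RR from oral-nasal pressure.

Quality gating follows the template-correlation scheme: a window is low
quality when its beat rhythm is physiologically implausible, or when the
mean correlation between individual beats and the window's average beat
template falls below a signal-specific threshold.

The reference detector band-passes the pressure signal to 4-60 breaths/min,
z-normalises each window, and marks inhalations at positive-gradient
crossings of a threshold ``k`` (default 0.42).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beats import detect_beats
from .core import BeatAnnotations, Waveform
from .filters import bandpass_bpm

#: template-correlation thresholds (empirical defaults, configurable)
CORRELATION_THRESHOLD = {"ecg": 0.66, "ppg": 0.86}
#: rhythm-plausibility limits
HR_BOUNDS = (30.0, 220.0)  # beats/min
MAX_INTERVAL_S = 3.0
MAX_INTERVAL_RATIO = 2.2
#: default inhalation-crossing threshold on the z-scored pressure signal
DEFAULT_K = 0.42
#: minimum fraction of window power inside 4-60 bpm for a usable pressure
#: window
MIN_BAND_POWER_FRACTION = 0.25


@dataclass
class WindowQuality:
    window_id: str
    is_high_quality: bool
    mean_template_correlation: float
    reason: str  # "plausibility" | "correlation" | "ok"


@dataclass
class ReferenceRR:
    window_id: str
    rr: float | None  # None = excluded
    k: float = DEFAULT_K


def beat_template_correlation(x: np.ndarray,
                              beats: BeatAnnotations) -> float:
    """Mean Pearson correlation of beat-centred segments with their mean.

    Segment width is the median beat-to-beat interval; beats whose segment
    would run off the window are skipped.
    """
    half = max(int(np.median(np.diff(beats.peak_idx)) // 2), 2)
    segs = [x[r - half:r + half] for r in beats.peak_idx
            if r - half >= 0 and r + half < x.size]
    if len(segs) < 2:
        return 0.0
    mat = np.asarray(segs, dtype=float)
    template = mat.mean(axis=0)
    ts = template - template.mean()
    tn = np.linalg.norm(ts)
    corrs = []
    for seg in mat:
        ss = seg - seg.mean()
        sn = np.linalg.norm(ss)
        corrs.append(float(ss @ ts / (sn * tn)) if sn > 0 and tn > 0
                     else 0.0)
    return float(np.mean(corrs))


def assess_window_quality(window: Waveform,
                          beats: BeatAnnotations | None = None,
                          window_id: str = "",
                          correlation_threshold: float | None = None
                          ) -> WindowQuality:
    """Two-stage quality gate: rhythm plausibility, then beat-template
    correlation."""
    if beats is None:
        beats = detect_beats(window)
    if not beats.valid or beats.n_beats < 2:
        return WindowQuality(window_id, False, 0.0, "plausibility")
    intervals = np.diff(beats.peak_idx) / window.fs
    hr = 60.0 / intervals.mean()
    implausible = (not HR_BOUNDS[0] <= hr <= HR_BOUNDS[1]
                   or intervals.max() > MAX_INTERVAL_S
                   or intervals.max() / intervals.min()
                   > MAX_INTERVAL_RATIO)
    if implausible:
        return WindowQuality(window_id, False, 0.0, "plausibility")
    corr = beat_template_correlation(window.samples, beats)
    if correlation_threshold is None:
        correlation_threshold = CORRELATION_THRESHOLD.get(
            window.signal_type, 0.66)
    if corr < correlation_threshold:
        return WindowQuality(window_id, False, corr, "correlation")
    return WindowQuality(window_id, True, corr, "ok")


# ---------------------------------------------------------------------------
# reference RR from oral-nasal pressure
# ---------------------------------------------------------------------------

def _band_power_fraction(x: np.ndarray, fs: float) -> float:
    x = x - x.mean()
    mag2 = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs) * 60.0
    total = mag2[1:].sum()
    if total <= 0:
        return 0.0
    band = (freqs >= 4.0) & (freqs <= 60.0)
    return float(mag2[band].sum() / total)


def znormalize(x: np.ndarray) -> np.ndarray:
    """Zero mean, unit standard deviation within the window."""
    sd = np.std(x)
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def threshold_crossings(x: np.ndarray, fs: float, k: float) -> np.ndarray:
    """Times of positive-gradient crossings of level ``k``."""
    above = x >= k
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    return idx / fs


def reference_rr(pressure_window: Waveform, k: float = DEFAULT_K,
                 window_id: str = "",
                 min_band_fraction: float = MIN_BAND_POWER_FRACTION,
                 ) -> ReferenceRR:
    """Reference RR for one pressure window; None when excluded.

    Windows whose 4-60 bpm band power fraction falls below
    ``min_band_fraction`` (poor signal-to-noise) are excluded, as are
    windows with fewer than two inhalation crossings.
    """
    if pressure_window.signal_type != "pressure":
        raise ValueError("reference RR requires a pressure waveform")
    x = bandpass_bpm(pressure_window.samples, pressure_window.fs, 4.0, 60.0)
    if _band_power_fraction(pressure_window.samples,
                            pressure_window.fs) < min_band_fraction:
        return ReferenceRR(window_id, None, k)
    z = znormalize(x)
    crossings = threshold_crossings(z, pressure_window.fs, k)
    if crossings.size < 2:
        return ReferenceRR(window_id, None, k)
    rr = 60.0 / float(np.mean(np.diff(crossings)))
    return ReferenceRR(window_id, rr, k)


def threshold_calibration(pressure_windows: list[Waveform],
                          annotated_breath_times: list[np.ndarray],
                          k_grid: np.ndarray | None = None) -> float:
    """Choose ``k`` minimising 2 x SD of (detector - annotation) RR.

    ``annotated_breath_times`` holds expert breath markers (seconds) per
    window; the annotation RR is 60 / mean inter-breath interval. Ties take
    the smallest grid value.
    """
    if not annotated_breath_times or not pressure_windows:
        raise ValueError("calibration requires annotated windows")
    if k_grid is None:
        k_grid = np.round(np.arange(0.10, 0.9001, 0.01), 10)
    ann_rr = []
    for t in annotated_breath_times:
        t = np.asarray(t, dtype=float)
        ann_rr.append(60.0 / np.mean(np.diff(t)) if t.size >= 2 else np.nan)
    ann_rr = np.asarray(ann_rr)
    best_k, best_crit = float(k_grid[0]), np.inf
    for k in k_grid:
        diffs = []
        for wf, rr_a in zip(pressure_windows, ann_rr):
            if not np.isfinite(rr_a):
                continue
            ref = reference_rr(wf, k=float(k))
            if ref.rr is not None:
                diffs.append(ref.rr - rr_a)
        if len(diffs) < 1:
            continue
        crit = 2.0 * float(np.std(diffs))
        if crit < best_crit - 1e-12:
            best_crit, best_k = crit, float(k)
    return best_k
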