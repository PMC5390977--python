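"""Extraction of respiratory signals from ECG/PPG windows.

Two families of techniques derive a time series dominated by respiratory
modulation from a raw cardiac waveform:

* filter-based (``xa1``-``xa4``): operate on the whole waveform — respiratory
  band-pass, continuous-wavelet-transform ridge amplitude/frequency within
  the cardiac band, or the centred-correntropy function;
* feature-based (``xb1``-``xb10``): measure one value per detected beat
  (peak/trough amplitudes, intervals, QRS duration/area, kernel-PCA score,
  pulse width), eliminate features from rhythm-outlier (ectopic) beats, and
  resample the irregular series onto a uniform 5 Hz grid.

Every extracted signal is finally band-passed to the plausible respiratory
band (4-60 breaths/min) and delivered at 5 Hz.
"""
from __future__ import annotations

import numpy as np
import pywt
from scipy import signal

from .beats import detect_beats
from .core import (BeatAnnotations, FeatureSeries, RespiratorySignal,
                   Waveform)
from .filters import bandpass_bpm, highpass, lowpass, notch, resample_to

RESP_FS = 5.0  # Hz, uniform rate of every extracted respiratory signal
_DECIM_FS = 25.0  # Hz, working rate for the filter-based techniques

FILTER_TECHNIQUES = ("xa1", "xa2", "xa3", "xa4")
#: techniques whose output is a lag function of the analysis window and
#: must therefore be recomputed per window rather than sliced from a
#: record-level extraction
PER_WINDOW_TECHNIQUES = ("xa4",)
FEATURE_TECHNIQUES = ("xb1", "xb2", "xb3", "xb4", "xb5", "xb6", "xb7",
                      "xb8", "xb9", "xb10")

#: which respiratory modulation(s) each technique is sensitive to
MODULATION_OF = {
    "xa1": "bw", "xa2": "am", "xa3": "fm", "xa4": "mixed",
    "xb1": "bw", "xb2": "am", "xb3": "fm", "xb4": "bw",
    "xb5": "mixed", "xb6": "mixed", "xb7": "fm", "xb8": "mixed",
    "xb9": "bw", "xb10": "fm",
}

#: signal types each extraction technique can operate on
COMPATIBLE_SIGNALS = {t: ("ecg", "ppg") for t in
                      FILTER_TECHNIQUES + FEATURE_TECHNIQUES}
COMPATIBLE_SIGNALS["xb7"] = ("ecg",)
COMPATIBLE_SIGNALS["xb8"] = ("ecg",)
COMPATIBLE_SIGNALS["xb10"] = ("ppg",)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(waveform: Waveform) -> Waveform:
    """Standard conditioning before any extraction technique.

    High-pass at 4 breaths/min to remove baseline drift below the
    respiratory band, low-pass at 100 Hz (ECG) or 35 Hz (PPG), and a 50 Hz
    mains notch for the ECG. Zero-phase throughout.
    """
    if waveform.signal_type not in ("ecg", "ppg"):
        raise ValueError("preprocess expects an ECG or PPG waveform")
    x = highpass(waveform.samples, waveform.fs, 4.0 / 60.0)
    if waveform.signal_type == "ecg":
        x = lowpass(x, waveform.fs, 100.0)
        x = notch(x, waveform.fs, 50.0)
    else:
        x = lowpass(x, waveform.fs, 35.0)
    return Waveform(x, waveform.fs, waveform.signal_type, t0=waveform.t0)


# ---------------------------------------------------------------------------
# filter-based techniques
# ---------------------------------------------------------------------------

def _finalize(values: np.ndarray, fs: float, technique: str,
              t0: float = 0.0) -> RespiratorySignal:
    """Respiratory band-pass then delivery at the common 5 Hz rate."""
    y = bandpass_bpm(values, fs, 4.0, 60.0, order=4)
    y = resample_to(y, fs, RESP_FS)
    return RespiratorySignal(y, RESP_FS, technique,
                             MODULATION_OF[technique], t0=t0)


def _cwt_ridge(x: np.ndarray, fs: float,
               lo_bpm: float = 30.0, hi_bpm: float = 220.0,
               voices: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample amplitude and frequency of the CWT ridge in the cardiac
    band, using an analytic Morlet wavelet with ``voices`` scales/octave."""
    wavelet = "cmor1.5-1.0"
    fc = pywt.central_frequency(wavelet)
    lo_hz, hi_hz = lo_bpm / 60.0, hi_bpm / 60.0
    n_scales = int(np.ceil(np.log2(hi_hz / lo_hz) * voices)) + 1
    freqs = np.geomspace(lo_hz, hi_hz, n_scales)
    scales = fc * fs / freqs
    coef, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs)
    mag = np.abs(coef)
    ridge = np.argmax(mag, axis=0)
    cols = np.arange(x.size)
    return mag[ridge, cols], freqs[ridge]


def _centred_correntropy(x: np.ndarray, fs: float,
                         max_lag_s: float = 31.0) -> np.ndarray:
    """Centred-correntropy lag function with a Gaussian kernel.

    Kernel bandwidth equals the standard deviation of the window (wide
    enough that slow baseline shifts, not only exact sample matches, drive
    the similarity). The centring term is the kernel mean over all sample
    pairs; the lag range spans almost the whole window so several
    respiratory cycles are represented.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    sigma = np.std(x)
    if sigma <= 0:
        sigma = 1.0
    inv = -0.5 / sigma ** 2
    diff = x[:, None] - x[None, :]
    kern = np.exp(inv * diff ** 2)
    centre = kern.mean()
    max_lag = min(int(max_lag_s * fs), n - 2)
    v = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        v[lag] = np.mean(np.diagonal(kern, offset=lag)) - centre
    return signal.detrend(v)


def extract_filter_based(waveform: Waveform,
                         technique: str) -> RespiratorySignal:
    """Filter-based respiratory-signal extraction (``xa1``-``xa4``)."""
    technique = technique.lower()
    if technique not in FILTER_TECHNIQUES:
        raise ValueError(f"unknown filter-based technique {technique!r}")
    fs = waveform.fs
    x = resample_to(waveform.samples, fs, _DECIM_FS)
    fs = _DECIM_FS
    if waveform.duration < 30.0:
        import warnings
        warnings.warn("window shorter than two respiratory cycles at 4 bpm;"
                      " extraction is low-confidence", stacklevel=2)

    if technique == "xa1":
        y = x
    elif technique in ("xa2", "xa3"):
        amp, freq = _cwt_ridge(x, fs)
        y = amp if technique == "xa2" else freq
    else:  # xa4
        y = _centred_correntropy(x, fs)
    return _finalize(y, fs, technique, t0=waveform.t0)


# ---------------------------------------------------------------------------
# feature-based techniques
# ---------------------------------------------------------------------------

def _trough_peak_pairs(waveform: Waveform, beats: BeatAnnotations):
    """Amplitudes and times of each (preceding trough, peak) pair."""
    x = waveform.samples
    peak_amp = x[beats.peak_idx]
    trough_amp = x[beats.trough_idx]
    t_peak = waveform.t0 + beats.peak_idx / waveform.fs
    return trough_amp, peak_amp, t_peak


def _kpca_first_component(segments: np.ndarray) -> np.ndarray:
    """Project beat segments on the first kernel principal component.

    RBF kernel; the kernel width is chosen on a 20-point log grid spanning
    [0.1, 10] x the median pairwise distance by maximising the difference
    between the first eigenvalue and the sum of the remainder.
    """
    n = segments.shape[0]
    sq = np.sum(segments ** 2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :]
                    - 2.0 * segments @ segments.T, 0.0)
    med = np.median(np.sqrt(d2[np.triu_indices(n, 1)]))
    if med <= 0:
        med = 1.0
    best_score, best_proj = -np.inf, None
    one = np.ones((n, n)) / n
    for sigma in np.geomspace(0.1 * med, 10 * med, 20):
        k = np.exp(-d2 / (2 * sigma ** 2))
        kc = k - one @ k - k @ one + one @ k @ one
        evals, evecs = np.linalg.eigh(kc)
        evals = evals[::-1]
        score = evals[0] - evals[1:].sum()
        if score > best_score:
            v1 = evecs[:, -1]
            best_score = score
            best_proj = kc @ v1
    return best_proj


def measure_feature(waveform: Waveform, beats: BeatAnnotations,
                    technique: str) -> FeatureSeries:
    """One feature value per beat (``xb1``-``xb10``)."""
    technique = technique.lower()
    if technique not in FEATURE_TECHNIQUES:
        raise ValueError(f"unknown feature technique {technique!r}")
    if waveform.signal_type not in COMPATIBLE_SIGNALS[technique]:
        raise ValueError(f"{technique} cannot operate on "
                         f"{waveform.signal_type} signals")
    if not beats.valid or beats.n_beats < 2:
        raise ValueError("feature measurement needs valid beat annotations")

    x = waveform.samples
    fs = waveform.fs
    trough_amp, peak_amp, t_peak = _trough_peak_pairs(waveform, beats)

    if technique == "xb1":  # mean of trough and proceeding peak (BW)
        return FeatureSeries(t_peak, (trough_amp + peak_amp) / 2.0,
                             technique)
    if technique == "xb2":  # peak-trough amplitude difference (AM)
        return FeatureSeries(t_peak, peak_amp - trough_amp, technique)
    if technique == "xb3":  # peak-to-peak interval (FM)
        return FeatureSeries(t_peak[1:], np.diff(t_peak), technique)
    if technique == "xb4":  # mean signal value between consecutive troughs
        tr = beats.trough_idx
        vals = [x[tr[i]:tr[i + 1] + 1].mean() for i in range(tr.size - 1)]
        times = waveform.t0 + (tr[:-1] + tr[1:]) / 2.0 / fs
        return FeatureSeries(times, np.asarray(vals), technique)
    if technique == "xb5":  # peak amplitude
        return FeatureSeries(t_peak, peak_amp, technique)
    if technique == "xb6":  # trough amplitude
        return FeatureSeries(t_peak, trough_amp, technique)
    if technique == "xb7":  # QRS duration
        dur = (beats.s_idx - beats.q_idx) / fs
        return FeatureSeries(t_peak, dur, technique)
    if technique == "xb8":  # QRS area above the Q-S baseline
        areas = []
        for q, s in zip(beats.q_idx, beats.s_idx):
            seg = x[q:s + 1]
            base = np.linspace(x[q], x[s], seg.size)
            areas.append(np.trapezoid(seg - base, dx=1.0 / fs))
        return FeatureSeries(t_peak, np.asarray(areas), technique)
    if technique == "xb9":  # kernel-PCA score of beat-aligned segments
        half = max(int(np.median(np.diff(beats.peak_idx)) // 2), 2)
        keep, segs = [], []
        for i, r in enumerate(beats.peak_idx):
            if r - half >= 0 and r + half < x.size:
                keep.append(i)
                segs.append(x[r - half:r + half])
        if len(segs) < 3:
            raise ValueError("too few complete beat segments for kPCA")
        proj = _kpca_first_component(np.asarray(segs))
        return FeatureSeries(t_peak[keep], proj, technique)
    # xb10: PPG pulse width between maximum-slope wave boundaries
    widths, times = [], []
    dx = np.gradient(x)
    for i, p in enumerate(beats.peak_idx):
        lo = beats.trough_idx[i]
        hi = beats.trough_idx[i + 1] if i + 1 < beats.n_beats else x.size - 1
        if p <= lo or hi <= p:
            continue
        onset = lo + int(np.argmax(dx[lo:p]))
        offset = p + int(np.argmin(dx[p:hi]))
        widths.append((offset - onset) / fs)
        times.append(t_peak[i])
    return FeatureSeries(np.asarray(times), np.asarray(widths), technique)


# ---------------------------------------------------------------------------
# ectopic elimination and resampling
# ---------------------------------------------------------------------------

def flag_ectopic(times: np.ndarray, tolerance: float = 0.3,
                 context: int = 10) -> np.ndarray:
    """Boolean mask of beats adjacent to a rhythm-outlier interval.

    A beat whose preceding interval deviates more than ``tolerance``
    (fractional) from the running median of the surrounding ``context``
    intervals is flagged, together with the beat that opens the interval.
    """
    times = np.asarray(times, dtype=float)
    flags = np.zeros(times.size, dtype=bool)
    if times.size < 3:
        return flags
    iv = np.diff(times)
    half = context // 2
    for i, d in enumerate(iv):
        lo, hi = max(i - half, 0), min(i + half + 1, iv.size)
        med = np.median(iv[lo:hi])
        if med > 0 and abs(d - med) > tolerance * med:
            flags[i] = flags[i + 1] = True
    return flags


def resample_uniform(times: np.ndarray, values: np.ndarray,
                     fs_out: float = RESP_FS
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto a uniform grid over [first, last] time."""
    grid = np.arange(times[0], times[-1] + 0.5 / fs_out, 1.0 / fs_out)
    return grid, np.interp(grid, times, values)


def clean_and_resample(features: FeatureSeries,
                       fs_out: float = RESP_FS) -> RespiratorySignal | None:
    """Ectopic elimination, 5 Hz resampling and respiratory band-passing.

    Returns ``None`` (the explicit no-output state) when fewer than three
    beats survive elimination.
    """
    if features.times.size < 3:
        return None
    keep = ~flag_ectopic(features.times)
    t, v = features.times[keep], features.values[keep]
    if t.size < 3:
        return None
    grid, y = resample_uniform(t, v, fs_out)
    if grid.size < 8:
        return None
    y = highpass(y, fs_out, 4.0 / 60.0)
    y = bandpass_bpm(y, fs_out, 4.0, 60.0, order=4)
    return RespiratorySignal(y, fs_out, features.technique,
                             MODULATION_OF[features.technique],
                             t0=float(grid[0]))


# ---------------------------------------------------------------------------
# high-level entry point
# ---------------------------------------------------------------------------

def extract_respiratory(window: Waveform, technique: str,
                        beats: BeatAnnotations | None = None,
                        preprocessed: bool = False
                        ) -> RespiratorySignal | None:
    """Full extraction path for one window and one technique.

    Preprocesses (unless told the window already is), detects beats when a
    feature-based technique needs them, and returns the final 5 Hz
    respiratory signal, or ``None`` when no output can be produced.
    """
    technique = technique.lower()
    wf = window if preprocessed else preprocess(window)
    if technique in FILTER_TECHNIQUES:
        return extract_filter_based(wf, technique)
    if technique not in FEATURE_TECHNIQUES:
        raise ValueError(f"unknown extraction technique {technique!r}")
    if beats is None:
        beats = detect_beats(wf)
    if not beats.valid or beats.n_beats < 3:
        return None
    feats = measure_feature(wf, beats, technique)
    return clean_and_resample(feats)
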