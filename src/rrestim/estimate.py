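"""RR estimation from one respiratory-signal window.

Frequency-domain techniques (``ef1``-``ef7``) locate the dominant spectral
component within 4-60 breaths/min; time-domain techniques (``et1``-``et5``)
detect individual breaths and convert the mean breath duration to a rate.
Any technique may decline to produce a value (returned as ``rr=None``),
e.g. on constant windows or when no spectral pole falls in the band.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RESP_BAND_BPM, RespiratorySignal, RREstimate
from .spectral import (ar_psd, band_peak, bpm_grid, burg, fft_spectrum,
                       poles_in_band, welch_spectrum)

FREQUENCY_TECHNIQUES = ("ef1", "ef2", "ef3", "ef4", "ef5", "ef6", "ef7")
TIME_TECHNIQUES = ("et1", "et2", "et3", "et4", "et5")
ESTIMATION_TECHNIQUES = FREQUENCY_TECHNIQUES + TIME_TECHNIQUES
#: techniques excluded from the default algorithm set by the verification
#: gate (lowest-frequency-pole selection is biased low outside 12-20 bpm)
EXCLUDED_ESTIMATION = ("ef5",)


@dataclass
class SpectrumEstimate:
    freqs: np.ndarray  # bpm
    power: np.ndarray
    method: str


@dataclass
class BreathTimes:
    times: np.ndarray  # seconds within the window
    #: breath durations, when the detector defines breaths as marker pairs
    #: rather than a contiguous marker train (et4); None = use diff(times)
    durations: np.ndarray | None = None


def _no_output(technique: str) -> RREstimate:
    return RREstimate(rr=None, technique_chain=(technique,))


def _result(rr: float | None, technique: str) -> RREstimate:
    lo, hi = RESP_BAND_BPM
    if rr is None or not np.isfinite(rr) or not lo <= rr <= hi:
        return _no_output(technique)
    return RREstimate(rr=float(rr), technique_chain=(technique,))


def _degenerate(x: np.ndarray) -> bool:
    return x.size < 16 or np.ptp(x) == 0 or not np.all(np.isfinite(x))


# ---------------------------------------------------------------------------
# frequency-domain estimation
# ---------------------------------------------------------------------------

def compute_spectrum(resp: RespiratorySignal,
                     technique: str) -> SpectrumEstimate | None:
    """Power/magnitude spectrum for the spectral-peak techniques."""
    x = resp.values
    fs = resp.fs
    if _degenerate(x):
        return None
    technique = technique.lower()
    if technique == "ef1":  # zero-padded Fourier magnitude
        freqs, mag = fft_spectrum(x, fs, nfft=2048)
        return SpectrumEstimate(freqs, mag, technique)
    if technique == "ef2":  # AR(8) spectral analysis
        a, var = burg(x, 8)
        grid = bpm_grid(fs)
        return SpectrumEstimate(grid, ar_psd(a, var, grid / 60.0, fs),
                                technique)
    if technique == "ef3":  # median AR spectrum over orders 2-20
        grid = bpm_grid(fs)
        psds = []
        for order in range(2, 21):
            if x.size <= order:
                break
            a, var = burg(x, order)
            psds.append(ar_psd(a, var, grid / 60.0, fs))
        if not psds:
            return None
        return SpectrumEstimate(grid, np.median(psds, axis=0), technique)
    if technique == "ef7":  # Welch periodogram, 3 half-overlapping segments
        freqs, power = welch_spectrum(x, fs)
        return SpectrumEstimate(freqs, power, technique)
    raise ValueError(f"no spectrum for technique {technique!r}")


def estimate_rr_spectral(resp: RespiratorySignal,
                         technique: str) -> RREstimate:
    """Spectral-peak RR estimation (``ef1``, ``ef2``, ``ef3``, ``ef6``,
    ``ef7``)."""
    technique = technique.lower()
    if technique == "ef6":
        return _estimate_rr_autocorrelation(resp)
    spec = compute_spectrum(resp, technique)
    if spec is None:
        return _no_output(technique)
    return _result(band_peak(spec.freqs, spec.power, *RESP_BAND_BPM),
                   technique)


def _estimate_rr_autocorrelation(resp: RespiratorySignal) -> RREstimate:
    """Periodicity via the highest autocorrelation peak in the band (ef6)."""
    x = resp.values
    fs = resp.fs
    if _degenerate(x):
        return _no_output("ef6")
    x = x - x.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    ac /= max(ac[0], np.finfo(float).tiny)
    lo_lag = max(int(np.floor(fs * 60.0 / RESP_BAND_BPM[1])), 1)
    hi_lag = min(int(np.ceil(fs * 60.0 / RESP_BAND_BPM[0])), ac.size - 2)
    if hi_lag <= lo_lag:
        return _no_output("ef6")
    seg = ac[lo_lag:hi_lag + 1]
    # highest local maximum; fall back to the plain maximum on monotone acf
    local = np.flatnonzero((seg[1:-1] >= seg[:-2]) & (seg[1:-1] > seg[2:]))
    idx = (local[np.argmax(seg[local + 1])] + 1) if local.size \
        else int(np.argmax(seg))
    lag = lo_lag + idx
    return _result(60.0 * fs / lag, "ef6")


def estimate_rr_pole(resp: RespiratorySignal, technique: str) -> RREstimate:
    """All-pole AR(8) RR estimation (``ef4`` highest-magnitude pole,
    ``ef5`` lowest-frequency pole)."""
    technique = technique.lower()
    if technique not in ("ef4", "ef5"):
        raise ValueError(f"not a pole technique: {technique!r}")
    x = resp.values
    if _degenerate(x) or x.size <= 8:
        return _no_output(technique)
    a, _ = burg(x, 8)
    cands = poles_in_band(a, resp.fs, *RESP_BAND_BPM)
    if not cands:
        return _no_output(technique)
    if technique == "ef4":
        freq, _ = max(cands, key=lambda fm: fm[1])
    else:
        freq, _ = min(cands, key=lambda fm: fm[0])
    return _result(freq, technique)


# ---------------------------------------------------------------------------
# time-domain breath detection
# ---------------------------------------------------------------------------

def _detrend(x: np.ndarray) -> np.ndarray:
    """Subtract the least-squares line over the window."""
    t = np.arange(x.size, dtype=float)
    coef = np.polyfit(t, x, 1)
    return x - np.polyval(coef, t)


def local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima by sign change of the first
    difference; plateaus take their first sample."""
    d = np.diff(x)
    # collapse zero differences to the sign of the next nonzero difference
    s = np.sign(d)
    for i in range(s.size - 2, -1, -1):
        if s[i] == 0:
            s[i] = s[i + 1]
    chg = np.diff(s)
    peaks = np.flatnonzero(chg < 0) + 1
    troughs = np.flatnonzero(chg > 0) + 1
    return peaks, troughs


def _et1(x: np.ndarray, fs: float) -> np.ndarray:
    """Breaths as signal peaks; peaks below the window mean are ignored."""
    peaks, _ = local_extrema(x)
    peaks = peaks[x[peaks] > x.mean()]
    return peaks / fs


def _et2(x: np.ndarray, fs: float) -> np.ndarray:
    """Breaths as positive-gradient crossings of the window mean level."""
    y = x - x.mean()
    cross = np.flatnonzero((y[:-1] < 0) & (y[1:] >= 0))
    return (cross + 1) / fs


def _et3(x: np.ndarray, fs: float) -> np.ndarray:
    """Combined peak-trough detection with three elimination rules applied
    in order: sub-mean peaks / super-mean troughs; markers within 0.5 s of
    the previous same-kind marker; markers immediately followed by a marker
    of the same kind."""
    peaks, troughs = local_extrema(x)
    mean = x.mean()
    peaks = peaks[x[peaks] >= mean]
    troughs = troughs[x[troughs] <= mean]

    def prune_close(idx: np.ndarray) -> np.ndarray:
        kept: list[int] = []
        for i in idx:
            if kept and (i - kept[-1]) / fs < 0.5:
                continue
            kept.append(int(i))
        return np.asarray(kept, dtype=int)

    peaks, troughs = prune_close(peaks), prune_close(troughs)
    # drop markers immediately followed by a marker of the same kind
    events = sorted([(int(i), "p") for i in peaks]
                    + [(int(i), "t") for i in troughs])
    keep_p, keep_t = [], []
    for j, (i, kind) in enumerate(events):
        if j + 1 < len(events) and events[j + 1][1] == kind:
            continue
        (keep_p if kind == "p" else keep_t).append(i)
    return np.asarray(keep_p, dtype=float) / fs


def _et4(x: np.ndarray, fs: float) -> np.ndarray:
    """'Count-orig': threshold peaks at 0.2 x the 75th percentile of peak
    values; a valid breath is two consecutive retained peaks separated by
    exactly one trough of negative amplitude. Returns the retained peak
    times bounding valid breaths and the valid breath durations."""
    peaks, troughs = local_extrema(x)
    if peaks.size == 0:
        return np.empty(0), np.empty(0)
    thr = 0.2 * np.percentile(x[peaks], 75)
    peaks = peaks[x[peaks] >= thr]
    markers: list[int] = []
    durations: list[float] = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        between = troughs[(troughs > a) & (troughs < b)]
        if between.size == 1 and x[between[0]] < 0:
            if not markers or markers[-1] != a:
                markers.append(int(a))
            markers.append(int(b))
            durations.append((b - a) / fs)
    return (np.asarray(markers, dtype=float) / fs,
            np.asarray(durations, dtype=float))


def _et5(x: np.ndarray, fs: float) -> np.ndarray:
    """'Count-adv': iteratively eliminate the consecutive-extrema pair with
    the smallest amplitude difference while it is below 0.3 x the 75th
    percentile of all initial consecutive differences."""
    peaks, troughs = local_extrema(x)
    kinds = np.concatenate([np.ones(peaks.size, dtype=int),
                            np.zeros(troughs.size, dtype=int)])
    idx = np.concatenate([peaks, troughs])
    order = np.argsort(idx)
    idx, kinds = list(idx[order]), list(kinds[order])
    if len(idx) < 2:
        return np.empty(0)
    diffs0 = np.abs(np.diff(x[np.asarray(idx)]))
    thr = 0.3 * np.percentile(diffs0, 75)
    while len(idx) >= 2:
        d = np.abs(np.diff(x[np.asarray(idx)]))
        j = int(np.argmin(d))
        if d[j] >= thr:
            break
        del idx[j:j + 2]
        del kinds[j:j + 2]
    out = [i for i, k in zip(idx, kinds) if k == 1]
    return np.asarray(out, dtype=float) / fs


_TIME_DETECTORS = {"et1": _et1, "et2": _et2, "et3": _et3, "et4": _et4,
                   "et5": _et5}


def detect_breaths(resp: RespiratorySignal, technique: str) -> BreathTimes:
    """Breath markers for one time-domain technique.

    ``et4``/``et5`` first detrend the window (least-squares line removal)
    per their published procedure.
    """
    technique = technique.lower()
    if technique not in _TIME_DETECTORS:
        raise ValueError(f"unknown time-domain technique {technique!r}")
    x = resp.values.astype(float)
    if _degenerate(x):
        return BreathTimes(times=np.empty(0))
    if technique in ("et4", "et5"):
        x = _detrend(x)
    if technique == "et4":
        times, durations = _et4(x, resp.fs)
        return BreathTimes(times=times, durations=durations)
    times = _TIME_DETECTORS[technique](x, resp.fs)
    return BreathTimes(times=np.asarray(times, dtype=float))


def breaths_to_rr(breaths: BreathTimes,
                  technique: str = "breaths") -> RREstimate:
    """RR = 60 / mean breath duration; no-output under two markers.

    Breath durations are the intervals between successive markers, except
    for detectors that delimit breaths as explicit marker pairs (et4),
    whose pair durations are averaged directly.
    """
    if breaths.durations is not None:
        if breaths.durations.size < 1:
            return _no_output(technique)
        return _result(60.0 / float(np.mean(breaths.durations)), technique)
    t = breaths.times
    if t.size < 2:
        return _no_output(technique)
    return _result(60.0 / np.mean(np.diff(t)), technique)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def estimate_rr(resp: RespiratorySignal, technique: str) -> RREstimate:
    """Run any single estimation technique on one window."""
    technique = technique.lower()
    if technique in ("ef1", "ef2", "ef3", "ef6", "ef7"):
        return estimate_rr_spectral(resp, technique)
    if technique in ("ef4", "ef5"):
        return estimate_rr_pole(resp, technique)
    if technique in TIME_TECHNIQUES:
        return breaths_to_rr(detect_breaths(resp, technique), technique)
    raise ValueError(f"unknown estimation technique {technique!r}")
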