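"""End-to-end orchestration: windowing, algorithm execution, verification.

A record is preprocessed once and its respiratory signals are extracted
over the full record (beats are detected once and shared); the respiratory
signals are then segmented into adjacent 32 s windows for estimation. The
correntropy technique is the exception — its output is a lag function of
the analysed span, so it is recomputed per window. Quality gating operates
on the raw-signal window. Window order is preserved so the temporal
smoother carries state across windows of one record.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assess import FUSION_TRIPLE, AlgorithmSpec
from .beats import detect_beats
from .core import RespiratorySignal, Waveform
from .estimate import compute_spectrum, estimate_rr
from .extract import (PER_WINDOW_TECHNIQUES, extract_respiratory,
                      preprocess)
from .fuse import (ModulationEstimates, TemporalSmoother, pole_fusion,
                   smart_fusion, spectral_peak_conditioned_average)
from .quality import assess_window_quality
from .spectral import burg, poles_in_band

logger = logging.getLogger(__name__)

WINDOW_LENGTH_S = 32.0
#: minimum respiratory-signal duration worth estimating from, seconds
_MIN_RESP_S = 16.0


@dataclass
class WindowSet:
    record_id: str
    windows: list  # (start_s, end_s) half-open, adjacent
    length: float = WINDOW_LENGTH_S


@dataclass
class WindowResult:
    window_id: str
    start_s: float
    rr: float | None
    state: str  # "ok" | "low_quality" | "no_output"
    technique_chain: tuple = field(default_factory=tuple)


def segment_windows(waveform: Waveform,
                    length_s: float = WINDOW_LENGTH_S,
                    record_id: str = "") -> WindowSet:
    """Adjacent half-open windows from t0; the final partial window is
    dropped."""
    n = int(np.floor(waveform.duration / length_s))
    if n == 0:
        logger.warning("record shorter than %.0f s; no windows", length_s)
    windows = [(waveform.t0 + i * length_s, waveform.t0 + (i + 1) * length_s)
               for i in range(n)]
    return WindowSet(record_id=record_id, windows=windows, length=length_s)


def record_respiratory(pre: Waveform, techniques, beats=None
                       ) -> dict[str, RespiratorySignal | None]:
    """Record-level respiratory signals for each requested technique.

    Per-window techniques map to None here and are computed later from the
    raw window.
    """
    need_beats = any(t.startswith("xb") for t in techniques)
    if beats is None and need_beats:
        beats = detect_beats(pre)
    out: dict[str, RespiratorySignal | None] = {}
    for t in techniques:
        if t in PER_WINDOW_TECHNIQUES:
            out[t] = None
            continue
        try:
            out[t] = extract_respiratory(pre, t, beats=beats,
                                         preprocessed=True)
        except ValueError:
            out[t] = None
    return out


def _window_signals(record_resp: dict, pre: Waveform, techniques,
                    start: float, end: float
                    ) -> dict[str, RespiratorySignal | None]:
    """Window views of the record-level signals (+ per-window recompute)."""
    out: dict[str, RespiratorySignal | None] = {}
    for t in techniques:
        if t in PER_WINDOW_TECHNIQUES:
            try:
                out[t] = extract_respiratory(pre.slice(start, end), t,
                                             preprocessed=True)
            except ValueError:
                out[t] = None
            continue
        sig = record_resp.get(t)
        if sig is not None:
            sig = sig.slice(start, end)
            if sig.duration < _MIN_RESP_S:
                sig = None
        out[t] = sig
    return out


def _fused_estimate(resp_by_mod: dict, spec: AlgorithmSpec) -> float | None:
    """Apply the modulation-fusion stage to the bw/am/fm triple."""
    sigs = [resp_by_mod.get(t) for t in FUSION_TRIPLE]
    if spec.mod_fusion == "fm1":
        rrs = [None if resp is None else estimate_rr(resp,
                                                     spec.estimation).rr
               for resp in sigs]
        return smart_fusion(ModulationEstimates(*rrs)).rr
    if spec.mod_fusion == "fm2":
        spectra = [compute_spectrum(r, "ef7") for r in sigs
                   if r is not None]
        spectra = [s for s in spectra if s is not None]
        if not spectra:
            return None
        return spectral_peak_conditioned_average(spectra).rr
    # fm3 / fm4: pool AR(8) poles across the three modulation signals
    poles = []
    for resp in sigs:
        if resp is None or resp.values.size <= 8 \
                or np.ptp(resp.values) == 0:
            continue
        a, _ = burg(resp.values, 8)
        poles.extend(poles_in_band(a, resp.fs))
    criterion = "magnitude" if spec.mod_fusion == "fm3" else "ranking"
    return pole_fusion(poles, criterion=criterion).rr


def estimate_from_signals(resp: dict, spec: AlgorithmSpec) -> float | None:
    """Raw (pre-smoothing) RR for one window given its extracted
    signals."""
    if spec.mod_fusion is not None:
        return _fused_estimate(resp, spec)
    sig = resp.get(spec.extraction[0])
    if sig is None:
        return None
    return estimate_rr(sig, spec.estimation).rr


def run_algorithm(record: Waveform, spec: AlgorithmSpec,
                  apply_quality_gate: bool = True,
                  length_s: float = WINDOW_LENGTH_S,
                  record_id: str = "") -> list[WindowResult]:
    """Run one algorithm over every window of a record.

    Low-quality windows yield an explicit excluded state; temporal
    smoothing (when selected) carries state across windows in order.
    """
    if record.signal_type not in spec.compatible_signals:
        raise ValueError(f"algorithm {spec.algorithm_id} cannot operate on "
                         f"{record.signal_type} records")
    pre = preprocess(record)
    resp_record = record_respiratory(pre, spec.extraction)
    windows = segment_windows(pre, length_s, record_id)
    smoother = TemporalSmoother() if spec.temp_fusion == "ft1" else None
    results = []
    for i, (start, end) in enumerate(windows.windows):
        wid = f"{record_id}:{i}"
        if apply_quality_gate:
            win = pre.slice(start, end)
            q = assess_window_quality(win, window_id=wid)
            if not q.is_high_quality:
                results.append(WindowResult(wid, start, None,
                                            "low_quality"))
                continue
        resp = _window_signals(resp_record, pre, spec.extraction, start,
                               end)
        rr = estimate_from_signals(resp, spec)
        if smoother is not None:
            rr = smoother.step(rr).rr
        state = "ok" if rr is not None else "no_output"
        results.append(WindowResult(wid, start, rr, state,
                                    spec.techniques))
    return results


# ---------------------------------------------------------------------------
# verification runner (simulated sweep)
# ---------------------------------------------------------------------------

def verification_errors(signals, specs: list[AlgorithmSpec],
                        window_start_s: float = 64.0,
                        length_s: float = WINDOW_LENGTH_S):
    """Absolute RR error of every algorithm on every simulated signal.

    One window per signal is scored (starting at ``window_start_s``, away
    from record edges). Extractions and beat detections are shared across
    algorithms, so the cost is one extraction per (signal, technique) and
    one estimate per (signal, distinct chain).

    Yields dict rows: algorithm_id, signal, modulation, hr, rr_true,
    rr_est, abs_error.
    """
    techniques_needed = sorted({t for s in specs for t in s.extraction})
    for sim in signals:
        cfg = sim.config
        pre = preprocess(sim.waveform)
        record_resp = record_respiratory(pre, techniques_needed)
        resp = _window_signals(record_resp, pre, techniques_needed,
                               window_start_s, window_start_s + length_s)
        est_cache: dict = {}
        for spec in specs:
            if cfg.signal_type not in spec.compatible_signals:
                continue
            key = (spec.extraction, spec.estimation, spec.mod_fusion)
            if key not in est_cache:
                est_cache[key] = estimate_from_signals(resp, spec)
            rr_est = est_cache[key]
            # a single window: ft1 passes the first estimate through
            err = abs(rr_est - cfg.rr) if rr_est is not None else np.nan
            yield {"algorithm_id": spec.algorithm_id,
                   "signal": cfg.signal_type,
                   "modulation": cfg.modulation,
                   "hr": cfg.hr, "rr_true": cfg.rr,
                   "rr_est": rr_est, "abs_error": err}
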