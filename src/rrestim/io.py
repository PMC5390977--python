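"""CSV/JSON input and output.

Waveforms travel as two-column CSV (``time_s,value``) with the sampling
rate inferred from the time column (or supplied); simulated records carry a
JSON manifest of their ground-truth configuration.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Waveform


def read_waveform_csv(path, signal_type: str,
                      fs: float | None = None) -> Waveform:
    """Read a ``time_s,value`` CSV; gaps or NaNs are rejected."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("expected columns time_s,value")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(~np.isfinite(v)) or np.any(~np.isfinite(t)):
        raise ValueError("waveform contains missing values")
    dt = np.diff(t)
    if fs is None:
        med = np.median(dt)
        if med <= 0 or np.any(np.abs(dt - med) > 0.01 * med):
            raise ValueError("time column is not uniformly sampled")
        fs = 1.0 / med
    return Waveform(v, fs, signal_type, t0=float(t[0]))


def write_waveform_csv(path, waveform: Waveform) -> None:
    pd.DataFrame({"time_s": waveform.times,
                  "value": waveform.samples}).to_csv(path, index=False)


def write_manifest(path, entries: list[dict]) -> None:
    """JSON manifest mapping record files to ground-truth settings."""
    def _default(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not serializable: {type(obj)}")
    Path(path).write_text(json.dumps(entries, indent=1, default=_default))


def write_estimates_csv(path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)
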