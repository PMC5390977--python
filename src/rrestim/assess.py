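"""Algorithm assembly, enumeration and the simulated-data verification gate.

An RR algorithm is a chain of one extraction technique (or the bw/am/fm
feature triple feeding a modulation-fusion technique), one estimation
technique where applicable, and optional temporal smoothing. The default
set excludes the two techniques that fail the simulated-data gate
(lowest-frequency-pole selection ``ef5`` and PPG pulse width ``xb10``).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimate import (ESTIMATION_TECHNIQUES, EXCLUDED_ESTIMATION)
from .extract import (COMPATIBLE_SIGNALS, FEATURE_TECHNIQUES,
                      FILTER_TECHNIQUES)

#: the bw/am/fm feature triple used by every modulation-fusion technique
FUSION_TRIPLE = ("xb1", "xb2", "xb3")
EXCLUDED_EXTRACTION = ("xb10",)


@dataclass(frozen=True)
class AlgorithmSpec:
    """One assembled RR algorithm."""

    extraction: tuple  # one technique, or the xb1/xb2/xb3 triple
    estimation: str | None  # None for fm2/fm3/fm4 (internal estimation)
    mod_fusion: str | None  # None | fm1..fm4
    temp_fusion: str | None  # None | ft1

    def __post_init__(self) -> None:
        if self.mod_fusion is not None and self.extraction != FUSION_TRIPLE:
            raise ValueError("modulation fusion requires the xb1/xb2/xb3 "
                             "extraction triple")
        if self.mod_fusion in ("fm2", "fm3", "fm4") \
                and self.estimation is not None:
            raise ValueError(f"{self.mod_fusion} carries its own "
                             "estimation stage")

    @property
    def compatible_signals(self) -> tuple:
        sigs = {"ecg", "ppg"}
        for x in self.extraction:
            sigs &= set(COMPATIBLE_SIGNALS[x])
        return tuple(sorted(sigs))

    @property
    def techniques(self) -> tuple:
        parts = list(self.extraction)
        if self.estimation:
            parts.append(self.estimation)
        if self.mod_fusion:
            parts.append(self.mod_fusion)
        if self.temp_fusion:
            parts.append(self.temp_fusion)
        return tuple(parts)

    @property
    def algorithm_id(self) -> str:
        ext = "+".join(self.extraction)
        bits = [ext, self.estimation or "-", self.mod_fusion or "-",
                self.temp_fusion or "-"]
        return "|".join(bits)


def enumerate_algorithms(include_excluded: bool = False
                         ) -> list[AlgorithmSpec]:
    """All algorithms constructible from the technique registry.

    Non-fusion algorithms pair each single extraction technique with each
    estimation technique; modulation-fusion algorithms run the xb1/xb2/xb3
    triple through smart fusion (any estimation technique) or through one
    of the spectral/pole fusion techniques (internal estimation). Every
    chain is emitted with and without temporal smoothing.
    """
    extractions = list(FILTER_TECHNIQUES + FEATURE_TECHNIQUES)
    estimations = list(ESTIMATION_TECHNIQUES)
    if not include_excluded:
        extractions = [x for x in extractions
                       if x not in EXCLUDED_EXTRACTION]
        estimations = [e for e in estimations
                       if e not in EXCLUDED_ESTIMATION]
    specs = []
    for temp in (None, "ft1"):
        for x in extractions:
            for e in estimations:
                specs.append(AlgorithmSpec((x,), e, None, temp))
        for e in estimations:
            specs.append(AlgorithmSpec(FUSION_TRIPLE, e, "fm1", temp))
        for fm in ("fm2", "fm3", "fm4"):
            specs.append(AlgorithmSpec(FUSION_TRIPLE, None, fm, temp))
    return specs


def count_signal_combinations(specs: list[AlgorithmSpec]) -> int:
    """Number of algorithm-signal pairs (both-signal specs count twice)."""
    return sum(len(s.compatible_signals) for s in specs)


# ---------------------------------------------------------------------------
# verification gate on simulated data
# ---------------------------------------------------------------------------

@dataclass
class VerificationReport:
    algorithm_acceptable: dict  # algorithm_id -> bool
    technique_fraction: dict  # technique -> fraction of algorithms passing
    technique_accepted: dict  # technique -> bool (fraction > 1/2)


def algorithm_acceptable(errors: pd.DataFrame,
                         max_abs_error: float = 1.0,
                         min_fraction: float = 0.5) -> bool:
    """Acceptability of one algorithm from its per-setting absolute errors.

    ``errors`` has columns ``signal``, ``modulation``, ``abs_error`` (NaN
    where the algorithm produced no output; counted as a failure). The
    algorithm is acceptable when, for at least one (modulation, signal)
    stratum, at least ``min_fraction`` of settings have absolute error
    <= ``max_abs_error`` bpm.
    """
    for (_, _), grp in errors.groupby(["modulation", "signal"]):
        err = grp["abs_error"].to_numpy(dtype=float)
        ok = np.where(np.isfinite(err), err <= max_abs_error, False)
        if ok.mean() >= min_fraction:
            return True
    return False


def verify_on_simulated(errors: pd.DataFrame,
                        specs: list[AlgorithmSpec],
                        max_abs_error: float = 1.0,
                        min_fraction: float = 0.5) -> VerificationReport:
    """Technique-level verification from per-algorithm error tables.

    ``errors`` has columns ``algorithm_id``, ``signal``, ``modulation``,
    ``abs_error``. A technique is accepted when more than half of the
    algorithms containing it are acceptably accurate.
    """
    by_alg = dict(tuple(errors.groupby("algorithm_id")))
    acceptable = {}
    for spec in specs:
        tab = by_alg.get(spec.algorithm_id)
        acceptable[spec.algorithm_id] = (
            algorithm_acceptable(tab, max_abs_error, min_fraction)
            if tab is not None else False)
    frac, accepted = {}, {}
    all_techniques = sorted({t for s in specs for t in s.techniques})
    for tech in all_techniques:
        members = [s for s in specs if tech in s.techniques]
        passing = sum(acceptable[s.algorithm_id] for s in members)
        frac[tech] = passing / len(members)
        accepted[tech] = frac[tech] > 0.5
    return VerificationReport(acceptable, frac, accepted)
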