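"""Ratiometric cytosolic-pH analysis for SNARF-1 loaded cells.

SNARF-1 emits at 580 and 630 nm with a pH-dependent ratio; an in vitro
calibration maps ln(F630/F580) linearly onto cytosolic pH.  Cells are
perfused through a schedule of external-pH phases (reference pH 8.15 at
both ends), and the pipeline derives per-phase cytosolic pH plateaus,
a drift QC on the flanking reference phases, the change in cytosolic
[H+] when cells are returned from acid to reference seawater (the
"Delta[H+]" efflux statistic), a responsive/defective classification on
that statistic, and two-sample Kolmogorov-Smirnov comparisons between
treatment populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Calibration",
    "Phase",
    "SNARFTrace",
    "EffluxResult",
    "ratio_to_ph",
    "ph_to_ratio",
    "drift_qc",
    "phase_response",
    "delta_h",
    "classify_efflux",
    "compare_distributions",
    "DEFECTIVE_THRESHOLD_M",
]

# printed defective-efflux threshold: Delta[H+] < 20 pM
DEFECTIVE_THRESHOLD_M = 20e-12


class SNARFError(ValueError):
    pass


@dataclass(frozen=True)
class Calibration:
    """pH = slope * ln(F630/F580) + intercept (in vitro SNARF-1 fit)."""

    slope: float = 0.8205
    intercept: float = 7.1101

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise SNARFError("calibration slope must be positive")


@dataclass(frozen=True)
class Phase:
    pH_o: float
    start: float  # s
    end: float  # s


@dataclass(frozen=True)
class SNARFTrace:
    """Dual-emission time series of one cell plus its perfusion schedule."""

    cell_id: str
    times: np.ndarray  # s
    F580: np.ndarray
    F630: np.ndarray
    phase_schedule: tuple[Phase, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f580 = np.asarray(self.F580, dtype=float)
        f630 = np.asarray(self.F630, dtype=float)
        for name, arr in (("times", t), ("F580", f580), ("F630", f630)):
            object.__setattr__(self, name, arr)
        if not (t.size == f580.size == f630.size):
            raise SNARFError("times and fluorescence arrays must align")
        if np.any(np.diff(t) <= 0):
            raise SNARFError("times must be strictly increasing")
        if np.any(f580 <= 0) or np.any(f630 <= 0):
            raise SNARFError("fluorescence must be positive")
        phases = sorted(self.phase_schedule, key=lambda p: p.start)
        for a, b in zip(phases, phases[1:]):
            if a.end > b.start:
                raise SNARFError("phases must not overlap")


@dataclass(frozen=True)
class EffluxResult:
    cell_id: str
    delta_H: float  # molar; positive = [H+] fell (net efflux)
    classification: str


def ratio_to_ph(F630, F580, cal: Calibration = Calibration()):
    """Cytosolic pH from the 630/580 nm emission pair (arrays ok)."""
    F630 = np.asarray(F630, dtype=float)
    F580 = np.asarray(F580, dtype=float)
    if np.any(F630 <= 0) or np.any(F580 <= 0):
        raise SNARFError("fluorescence must be positive")
    out = cal.slope * np.log(F630 / F580) + cal.intercept
    return float(out) if out.ndim == 0 else out


def ph_to_ratio(pH, cal: Calibration = Calibration()):
    """Inverse calibration: emission ratio F630/F580 producing `pH`."""
    pH = np.asarray(pH, dtype=float)
    out = np.exp((pH - cal.intercept) / cal.slope)
    return float(out) if out.ndim == 0 else out


def _ph_trace(trace: SNARFTrace, cal: Calibration) -> np.ndarray:
    return ratio_to_ph(trace.F630, trace.F580, cal)


def _window_mean(
    trace: SNARFTrace, ph: np.ndarray, phase: Phase, window: float
) -> float:
    if phase.end - phase.start < window:
        raise SNARFError(
            f"phase [{phase.start}, {phase.end}] s shorter than the "
            f"{window} s analysis window"
        )
    mask = (trace.times >= phase.end - window) & (trace.times <= phase.end)
    if not mask.any():
        raise SNARFError("no samples inside the end-of-phase window")
    return float(ph[mask].mean())


def _reference_phases(
    trace: SNARFTrace, reference_pH: float, tol: float = 1e-6
) -> tuple[Phase, Phase]:
    phases = sorted(trace.phase_schedule, key=lambda p: p.start)
    if len(phases) < 2:
        raise SNARFError("schedule must contain at least two phases")
    first, last = phases[0], phases[-1]
    for which, p in (("first", first), ("last", last)):
        if abs(p.pH_o - reference_pH) > tol:
            raise SNARFError(
                f"{which} phase is pH {p.pH_o}, not the reference {reference_pH}"
            )
    return first, last


def drift_qc(
    trace: SNARFTrace,
    cal: Calibration = Calibration(),
    max_offset: float = 0.04,
    reference_pH: float = 8.15,
    window: float = 30.0,
) -> bool:
    """Pass iff the cytosolic pH offset between the flanking reference
    phases is <= `max_offset` (default 4%), relative to the starting pH.
    """
    first, last = _reference_phases(trace, reference_pH)
    ph = _ph_trace(trace, cal)
    start = _window_mean(trace, ph, first, window)
    end = _window_mean(trace, ph, last, window)
    return abs(end - start) / start <= max_offset


def phase_response(
    trace: SNARFTrace, cal: Calibration = Calibration(), window: float = 30.0
) -> dict[float, float]:
    """Mean cytosolic pH over the final `window` s of each perfusion phase.

    Later phases at the same external pH overwrite earlier ones only in
    the key; use the list form of the schedule if both are needed.
    """
    ph = _ph_trace(trace, cal)
    return {
        p.pH_o: _window_mean(trace, ph, p, window)
        for p in sorted(trace.phase_schedule, key=lambda p: p.start)
    }


def delta_h(
    trace: SNARFTrace,
    cal: Calibration = Calibration(),
    from_pH_o: float = 6.5,
    to_pH_o: float = 8.15,
    window: float = 30.0,
    tol: float = 1e-6,
) -> float:
    """Change in cytosolic [H+] (molar) on transfer between two phases.

    10**(-pH_from) - 10**(-pH_to) using end-of-phase window means, the
    `to` phase being the first one scheduled after the `from` phase.
    Positive values mean [H+] fell after the transfer, i.e. net efflux.
    """
    phases = sorted(trace.phase_schedule, key=lambda p: p.start)
    ph = _ph_trace(trace, cal)
    from_phase = next(
        (p for p in phases if abs(p.pH_o - from_pH_o) <= tol), None
    )
    if from_phase is None:
        raise SNARFError(f"no phase at pH_o {from_pH_o} in the schedule")
    to_phase = next(
        (
            p for p in phases
            if p.start >= from_phase.end and abs(p.pH_o - to_pH_o) <= tol
        ),
        None,
    )
    if to_phase is None:
        raise SNARFError(f"no pH_o {to_pH_o} phase after the pH_o {from_pH_o} one")
    ph_from = _window_mean(trace, ph, from_phase, window)
    ph_to = _window_mean(trace, ph, to_phase, window)
    return 10.0 ** (-ph_from) - 10.0 ** (-ph_to)


def classify_efflux(
    delta_H: float, threshold: float = DEFECTIVE_THRESHOLD_M
) -> str:
    """'defective' iff Delta[H+] < threshold (default 20 pM, strict)."""
    return "defective" if delta_H < threshold else "responsive"


def compare_distributions(
    deltas_a: Sequence[float], deltas_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test on Delta[H+] samples."""
    a = np.asarray(deltas_a, dtype=float)
    b = np.asarray(deltas_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise SNARFError("need >= 5 cells per sample for the KS comparison")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
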