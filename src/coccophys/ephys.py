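"""Whole-cell voltage-clamp analysis.

Takes current families recorded under step protocols (by default 1-s
10-mV depolarizations from -80 to +40 mV), subtracts the linear seal
leak, extracts steady-state current-voltage relations normalized to
cell capacitance (pA/pF), classifies cells by the size of their outward
current at +45 mV, fits tail-current reversal potentials, and applies
the series-resistance stability criterion used to accept recordings.

Sign convention: outward current is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "VoltageProtocol",
    "CellRecording",
    "IVCurve",
    "leak_subtract",
    "iv_curve",
    "classify_outward",
    "density_at",
    "tail_reversal_potential",
    "tail_peaks_from_sweeps",
    "series_resistance_qc",
    "DEFECTIVE_THRESHOLD_PA_PF",
    "CLASSIFICATION_VOLTAGE_MV",
]

DEFECTIVE_THRESHOLD_PA_PF = 2.5
CLASSIFICATION_VOLTAGE_MV = 45.0


class EphysError(ValueError):
    pass


@dataclass(frozen=True)
class VoltageProtocol:
    holding: float = -80.0
    step_levels: tuple[float, ...] = tuple(float(v) for v in range(-80, 41, 10))
    step_duration: float = 1000.0  # ms
    tail_level: float | None = None

    def __post_init__(self) -> None:
        if not all(b > a for a, b in zip(self.step_levels, self.step_levels[1:])):
            raise EphysError("step levels must be strictly increasing")
        if self.step_duration <= 0:
            raise EphysError("step duration must be positive")


@dataclass(frozen=True)
class CellRecording:
    """One cell's sweep family: time x step current matrix in pA.

    Cm in pF, R_seal in GOhm; Rs_series (MOhm over the recording) is
    optional and only used by the QC stage.
    """

    protocol: VoltageProtocol
    sweeps: np.ndarray
    sample_interval: float  # ms
    Cm: float
    R_seal: float | None
    Rs_series: tuple[float, ...] | None = None
    leak_subtracted: bool = False
    cell_id: str = ""

    def __post_init__(self) -> None:
        sw = np.asarray(self.sweeps, dtype=float)
        object.__setattr__(self, "sweeps", sw)
        if sw.ndim != 2 or sw.shape[1] != len(self.protocol.step_levels):
            raise EphysError(
                "sweep matrix must be time x step with one column per level"
            )
        if self.Cm <= 0:
            raise EphysError("Cm must be positive")
        if self.R_seal is not None and self.R_seal <= 0:
            raise EphysError("R_seal must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.sweeps.shape[0]) * self.sample_interval


@dataclass(frozen=True)
class IVCurve:
    voltages: tuple[float, ...]
    current_density: tuple[float, ...]  # pA/pF
    E_rev: float | None = None
    classification: str | None = None

    def __post_init__(self) -> None:
        if len(self.voltages) != len(self.current_density):
            raise EphysError("one density per voltage required")


def leak_subtract(rec: CellRecording) -> CellRecording:
    """Remove the ohmic seal leak (V_step - holding)/R_seal from each sweep.

    R_seal in GOhm and voltages in mV give leak currents directly in pA.
    """
    if rec.R_seal is None:
        raise EphysError("R_seal required for leak subtraction")
    steps = np.asarray(rec.protocol.step_levels)
    leak = (steps - rec.protocol.holding) / rec.R_seal  # pA, per column
    return replace(rec, sweeps=rec.sweeps - leak[None, :], leak_subtracted=True)


def iv_curve(rec: CellRecording, window_start: float = 500.0) -> IVCurve:
    """Steady-state I-V: signed extremum after `window_start` ms, per step.

    The outward conductance activates slowly, so the extremum of the
    late window approximates the steady-state current; it is signed (the
    value of largest magnitude is kept) and normalized by Cm to pA/pF.
    """
    if not rec.leak_subtracted:
        raise EphysError("leak-subtract the recording before I-V extraction")
    if rec.protocol.step_duration < window_start:
        raise EphysError("step shorter than the measurement window")
    i0 = int(np.ceil(window_start / rec.sample_interval))
    if i0 >= rec.sweeps.shape[0]:
        raise EphysError("measurement window is empty")
    late = rec.sweeps[i0:, :]
    idx = np.argmax(np.abs(late), axis=0)
    extremum = late[idx, np.arange(late.shape[1])]
    return IVCurve(
        voltages=tuple(rec.protocol.step_levels),
        current_density=tuple(extremum / rec.Cm),
    )


def density_at(iv: IVCurve, voltage: float, max_extrapolation: float = 10.0) -> float:
    """Current density at an arbitrary voltage by linear interpolation.

    Extrapolates at most `max_extrapolation` mV beyond the last step
    using the final segment's slope; beyond that it errors.
    """
    v = np.asarray(iv.voltages)
    d = np.asarray(iv.current_density)
    if v.size < 2:
        raise EphysError("need >= 2 I-V points")
    if v[0] <= voltage <= v[-1]:
        return float(np.interp(voltage, v, d))
    if voltage > v[-1] and voltage - v[-1] <= max_extrapolation:
        slope = (d[-1] - d[-2]) / (v[-1] - v[-2])
        return float(d[-1] + slope * (voltage - v[-1]))
    if voltage < v[0] and v[0] - voltage <= max_extrapolation:
        slope = (d[1] - d[0]) / (v[1] - v[0])
        return float(d[0] + slope * (voltage - v[0]))
    raise EphysError(
        f"{voltage} mV is more than {max_extrapolation} mV outside the protocol"
    )


def classify_outward(
    iv: IVCurve,
    threshold: float = DEFECTIVE_THRESHOLD_PA_PF,
    at_voltage: float = CLASSIFICATION_VOLTAGE_MV,
) -> str:
    """'defective' iff the outward density at +45 mV is < 2.5 pA/pF.

    +45 mV sits 5 mV above the top protocol step, so the density there
    is obtained by bounded linear extrapolation of the last segment.
    The comparison is strict: exactly threshold is 'responsive'.
    """
    return "defective" if density_at(iv, at_voltage) < threshold else "responsive"


def tail_reversal_potential(
    tail_peaks: Sequence[tuple[float, float]],
) -> float:
    """Reversal potential (mV) as the x-intercept of peak tail current vs V.

    Least-squares line through (tail voltage, peak tail current) pairs;
    needs >= 3 voltages and a non-zero slope.
    """
    pts = np.asarray(tail_peaks, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise EphysError("need >= 3 (voltage, current) tail points")
    v, i = pts[:, 0], pts[:, 1]
    slope, intercept = np.polyfit(v, i, 1)
    if abs(slope) < 1e-12 * max(1.0, float(np.max(np.abs(i)))):
        raise EphysError("tail currents do not depend on voltage: no reversal")
    return float(-intercept / slope)


def tail_peaks_from_sweeps(
    sweeps: np.ndarray,
    tail_voltages: Sequence[float],
    sample_interval: float,
    tail_start: float,
    blank: float = 2.0,
    window: float = 20.0,
) -> list[tuple[float, float]]:
    """Extract per-sweep peak tail currents.

    The peak is the signed extremum within `window` ms after the tail
    step, skipping a `blank` ms capacitive-transient window.
    """
    i0 = int(np.ceil((tail_start + blank) / sample_interval))
    i1 = int(np.floor((tail_start + window) / sample_interval)) + 1
    if i1 <= i0 or i0 >= sweeps.shape[0]:
        raise EphysError("tail window is empty")
    seg = sweeps[i0:i1, :]
    idx = np.argmax(np.abs(seg), axis=0)
    peaks = seg[idx, np.arange(seg.shape[1])]
    return [(float(v), float(p)) for v, p in zip(tail_voltages, peaks)]


def series_resistance_qc(
    rec: CellRecording, max_variation: float = 0.15
) -> bool | None:
    """Accept the recording iff Rs varied by <= 15% of its initial value.

    Returns True (pass), False (fail), or None when no Rs series was
    recorded (indeterminate).
    """
    if rec.Rs_series is None or len(rec.Rs_series) == 0:
        return None
    rs = np.asarray(rec.Rs_series, dtype=float)
    variation = (rs.max() - rs.min()) / rs[0]
    return bool(variation <= max_variation)
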