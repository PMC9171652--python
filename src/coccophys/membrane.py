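"""Plasma-membrane proton electrochemistry.

The driving force on H+ across the plasma membrane combines the
membrane potential V_m with the transmembrane pH gradient.  With
DeltapH = pH_cyt - pH_o, the Nernst equilibrium potential is

    E_H = (2.303 R T / F) * DeltapH        [mV]

and the proton motive force, signed so that positive values drive H+
out of the cell,

    pmf = -(2.303 R T / F) * DeltapH + V_m = V_m - E_H.

Because voltage-gated H+ channels only pass outward current at
potentials positive of E_H, the seawater pH at which pmf crosses zero
marks where passive H+ efflux becomes unfavourable — the quantity of
interest for cells in acidified seawater.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

R_GAS = 8.3145  # J/mol/K
FARADAY = 96485.0  # C/mol

__all__ = [
    "MembraneState",
    "nernst_slope",
    "nernst_eh",
    "pmf",
    "pmf_zero_ph",
    "pmf_envelope",
    "activation_potential",
]


class MembraneError(ValueError):
    pass


@dataclass(frozen=True)
class MembraneState:
    """pH on either side of the membrane plus V_m (mV) and T (deg C)."""

    pH_cyt: float
    pH_o: float
    V_m: float
    temperature: float = 15.0
    z: int = 1

    def __post_init__(self) -> None:
        for name, v in (("pH_cyt", self.pH_cyt), ("pH_o", self.pH_o)):
            if not (5.0 <= v <= 10.0):
                raise MembraneError(f"{name}={v} outside [5, 10]")
        if not (-120.0 <= self.V_m <= 60.0):
            raise MembraneError(f"V_m={self.V_m} mV outside [-120, +60]")


def nernst_slope(temperature: float = 15.0) -> float:
    """2.303 RT/F in mV per pH unit (~57.2 mV at 15 degC)."""
    if not (-2.0 <= temperature <= 40.0):
        raise MembraneError(f"temperature {temperature} degC outside [-2, 40]")
    return 2.303 * R_GAS * (temperature + 273.15) / FARADAY * 1e3


def nernst_eh(state: MembraneState) -> float:
    """H+ equilibrium potential E_H (mV)."""
    return nernst_slope(state.temperature) * (state.pH_cyt - state.pH_o) / state.z


def pmf(state: MembraneState) -> float:
    """Proton motive force (mV); positive = outward driving force on H+."""
    return state.V_m - nernst_eh(state)


def pmf_zero_ph(pH_cyt: float, V_m: float, temperature: float = 15.0) -> float:
    """Seawater pH at which the pmf crosses zero (closed form).

    pmf = 0  <=>  pH_o = pH_cyt - V_m / (2.303 RT/F).
    """
    return pH_cyt - V_m / nernst_slope(temperature)


def pmf_envelope(
    pH_o_grid: Iterable[float],
    pH_cyt_bounds: Sequence[float] = (6.8, 7.1),
    V_m_bounds: Sequence[float] = (-46.0, -28.0),
    temperature: float = 15.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pH_o (min, max) pmf over the four (pH_cyt, V_m) corner models.

    Defaults are the measured extremes for C. braarudii: cytosolic pH
    6.8-7.1 and resting V_m -46 to -28 mV.
    """
    if pH_cyt_bounds[0] > pH_cyt_bounds[1] or V_m_bounds[0] > V_m_bounds[1]:
        raise MembraneError("bounds must be (low, high)")
    grid = np.asarray(list(pH_o_grid), dtype=float)
    slope = nernst_slope(temperature)
    corners = np.stack([
        vm - slope * (phc - grid)
        for phc in pH_cyt_bounds
        for vm in V_m_bounds
    ])
    return corners.min(axis=0), corners.max(axis=0)


def activation_potential(E_H: float, offset: float = 0.0) -> float:
    """Hv-channel activation potential, modelled as tracking E_H + offset."""
    return E_H + offset
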