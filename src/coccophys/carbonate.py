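"""Seawater CO2-system solver.

Solves the marine carbonate system (CO2*, HCO3-, CO3--, borate, water
self-ionization, sulfate and fluoride side reactions) from any of the
measured pairs used in culture work — (pH_NBS, TA) or (DIC, TA) — and
computes the calcite saturation state Omega.  It also models the
experimental manipulation used to set culture pH: adding strong acid or
base, which changes total alkalinity at constant DIC.

Equilibrium constants follow one widely used parameterization:

* K1, K2    Lueker, Dickson & Keeling (2000), total scale
* KB        Dickson (1990b), total scale
* KW        Millero (1995), seawater scale (converted to total)
* KS        Dickson (1990a), free scale
* KF        Dickson & Riley (1979), free scale
* K0        Weiss (1974)
* Ksp       Mucci (1983), calcite
* BT        Uppstrom (1974); CaT Riley & Tongudai (1967);
  ST Morris & Riley (1966); FT Riley (1965)

Internally all proton concentrations are on the total scale; the NBS
scale used by bench pH meters is bridged through the Takahashi et al.
(1982) activity coefficient fH.  Concentrations are mol/kg-SW internally
and umol/kg at the API surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = [
    "SeawaterConditions",
    "ConstantSet",
    "CarbonateSystem",
    "equilibrium_constants",
    "solve_from_ph_ta",
    "solve_from_dic_ta",
    "ta_for_target_ph",
    "omega_calcite",
]


class CarbonateError(ValueError):
    """Raised for out-of-range inputs or infeasible carbonate states."""


@dataclass(frozen=True)
class SeawaterConditions:
    """Physical state of the seawater sample.

    temperature : deg C, valid -2..40
    salinity    : practical salinity, valid 1..45
    pressure    : dbar; culture flasks sit at the surface so 0 throughout
    """

    temperature: float = 15.0
    salinity: float = 35.0
    pressure: float = 0.0

    def __post_init__(self) -> None:
        if not (-2.0 <= self.temperature <= 40.0):
            raise CarbonateError(
                f"temperature {self.temperature} degC outside [-2, 40]"
            )
        if not (1.0 <= self.salinity <= 45.0):
            raise CarbonateError(f"salinity {self.salinity} outside [1, 45]")


@dataclass(frozen=True)
class ConstantSet:
    """Equilibrium constants (total scale unless noted) and totals, mol/kg-SW."""

    K0: float  # mol/kg/atm, CO2 solubility
    K1: float
    K2: float
    KB: float
    KW: float
    KS: float  # free scale (bisulfate)
    KF: float  # free scale (HF)
    Ksp_calcite: float  # mol^2/kg^2
    BT: float
    CaT: float
    ST: float
    FT: float
    fH: float  # NBS activity coefficient bridge
    parameterization: str = "Lueker00/Dickson90/Millero95/Mucci83"

    def __post_init__(self) -> None:
        for name in ("K0", "K1", "K2", "KB", "KW", "KS", "KF", "Ksp_calcite"):
            if getattr(self, name) <= 0:
                raise CarbonateError(f"constant {name} must be positive")
        if self.K1 <= self.K2:
            raise CarbonateError("K1 must exceed K2")

    @property
    def sws_to_total(self) -> float:
        """Multiplier taking [H+]_SWS to [H+]_total."""
        return (1.0 + self.ST / self.KS) / (
            1.0 + self.ST / self.KS + self.FT / self.KF
        )

    @property
    def free_to_total(self) -> float:
        return 1.0 + self.ST / self.KS


@dataclass(frozen=True)
class CarbonateSystem:
    """Fully speciated CO2 system.  pH on the NBS scale; amounts in umol/kg."""

    conditions: SeawaterConditions
    pH: float
    TA: float
    DIC: float
    CO2: float
    HCO3: float
    CO3: float
    omega_calcite: float
    parameterization: str = "Lueker00/Dickson90/Millero95/Mucci83"

    def __post_init__(self) -> None:
        if min(self.CO2, self.HCO3, self.CO3) < 0:
            raise CarbonateError("negative carbonate species")
        if abs(self.CO2 + self.HCO3 + self.CO3 - self.DIC) > 1e-9 * max(self.DIC, 1.0):
            raise CarbonateError("species do not sum to DIC")
        if self.omega_calcite < 0:
            raise CarbonateError("negative saturation state")


def equilibrium_constants(conditions: SeawaterConditions) -> ConstantSet:
    """Evaluate the constant parameterization at the sample's T and S.

    Deterministic closed forms; no pressure corrections (surface only).
    """
    S = conditions.salinity
    TK = conditions.temperature + 273.15
    lnTK = math.log(TK)
    sqS = math.sqrt(S)

    # ionic strength from salinity
    IonS = 19.924 * S / (1000.0 - 1.005 * S)
    sqI = math.sqrt(IonS)

    # totals, mol/kg-SW
    ST = 0.14 / 96.062 * S / 1.80655
    FT = 0.000067 / 18.998 * S / 1.80655
    BT = 0.0004157 * S / 35.0
    CaT = 0.02128 / 40.087 * S / 1.80655

    # bisulfate (Dickson 1990a), free scale
    lnKS = (
        -4276.1 / TK + 141.328 - 23.093 * lnTK
        + (-13856.0 / TK + 324.57 - 47.986 * lnTK) * sqI
        + (35474.0 / TK - 771.54 + 114.723 * lnTK) * IonS
        - 2698.0 / TK * IonS ** 1.5
        + 1776.0 / TK * IonS ** 2
        + math.log(1.0 - 0.001005 * S)
    )
    KS = math.exp(lnKS)

    # hydrogen fluoride (Dickson & Riley 1979), free scale
    lnKF = 1590.2 / TK - 12.641 + 1.525 * sqI + math.log(1.0 - 0.001005 * S)
    KF = math.exp(lnKF)

    free_to_total = 1.0 + ST / KS
    sws_to_total = free_to_total / (1.0 + ST / KS + FT / KF)

    # CO2 solubility (Weiss 1974)
    TK100 = TK / 100.0
    lnK0 = (
        -60.2409 + 93.4517 / TK100 + 23.3585 * math.log(TK100)
        + S * (0.023517 - 0.023656 * TK100 + 0.0047036 * TK100 ** 2)
    )
    K0 = math.exp(lnK0)

    # carbonic acid (Lueker et al. 2000), total scale
    pK1 = 3633.86 / TK - 61.2172 + 9.67770 * lnTK - 0.011555 * S + 0.0001152 * S ** 2
    pK2 = 471.78 / TK + 25.9290 - 3.16967 * lnTK - 0.01781 * S + 0.0001122 * S ** 2
    K1 = 10.0 ** (-pK1)
    K2 = 10.0 ** (-pK2)

    # boric acid (Dickson 1990b), total scale
    lnKB = (
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S ** 1.5 - 0.0996 * S ** 2)
        / TK
        + 148.0248 + 137.1942 * sqS + 1.62142 * S
        + (-24.4344 - 25.085 * sqS - 0.2474 * S) * lnTK
        + 0.053105 * sqS * TK
    )
    KB = math.exp(lnKB)

    # water (Millero 1995), SWS scale -> total
    lnKW = (
        148.9802 - 13847.26 / TK - 23.6521 * lnTK
        + (118.67 / TK - 5.977 + 1.0495 * lnTK) * sqS
        - 0.01615 * S
    )
    KW = math.exp(lnKW) * sws_to_total

    # calcite solubility (Mucci 1983)
    log10Ksp = (
        -171.9065 - 0.077993 * TK + 2839.319 / TK + 71.595 * math.log10(TK)
        + (-0.77712 + 0.0028426 * TK + 178.34 / TK) * sqS
        - 0.07711 * S
        + 0.0041249 * S ** 1.5
    )
    Ksp = 10.0 ** log10Ksp

    # NBS bridge (Takahashi et al. 1982)
    fH = 1.2948 - 0.002036 * TK + (0.0004607 - 0.000001475 * TK) * S ** 2

    return ConstantSet(
        K0=K0, K1=K1, K2=K2, KB=KB, KW=KW, KS=KS, KF=KF,
        Ksp_calcite=Ksp, BT=BT, CaT=CaT, ST=ST, FT=FT, fH=fH,
    )


def _h_total_from_nbs(pH_nbs: float, k: ConstantSet) -> float:
    """NBS pH (activity) -> total-scale [H+], mol/kg."""
    h_sws = 10.0 ** (-pH_nbs) / k.fH
    return h_sws * k.sws_to_total


def _nbs_from_h_total(h_total: float, k: ConstantSet) -> float:
    h_sws = h_total / k.sws_to_total
    return -math.log10(h_sws * k.fH)


def _noncarbonate_alkalinity(h: float, k: ConstantSet) -> float:
    """Borate + OH - Hfree - HSO4 - HF at total-scale [H+] h, mol/kg."""
    borate = k.BT * k.KB / (k.KB + h)
    oh = k.KW / h
    h_free = h / k.free_to_total
    hso4 = k.ST / (1.0 + k.KS / h_free)
    hf = k.FT / (1.0 + k.KF / h_free)
    return borate + oh - h_free - hso4 - hf


def _speciate(dic: float, h: float, k: ConstantSet) -> tuple[float, float, float]:
    """Partition DIC (mol/kg) among CO2*, HCO3-, CO3-- at total-scale [H+]."""
    denom = h * h + k.K1 * h + k.K1 * k.K2
    co2 = dic * h * h / denom
    hco3 = dic * k.K1 * h / denom
    co3 = dic * k.K1 * k.K2 / denom
    return co2, hco3, co3


def solve_from_ph_ta(
    pH: float,
    TA: float,
    conditions: SeawaterConditions | None = None,
    constants: ConstantSet | None = None,
) -> CarbonateSystem:
    """Speciate from measured pH_NBS and total alkalinity (umol/kg).

    At fixed pH every alkalinity term except the carbonate one is known,
    so DIC follows without iteration from

        TA - TA_noncarb = DIC * (K1 h + 2 K1 K2) / (h^2 + K1 h + K1 K2).
    """
    if not (6.0 <= pH <= 9.5):
        raise CarbonateError(f"pH {pH} outside [6, 9.5]")
    if not (0.0 < TA <= 5000.0):
        raise CarbonateError(f"TA {TA} umol/kg outside (0, 5000]")
    conditions = conditions or SeawaterConditions()
    k = constants or equilibrium_constants(conditions)

    h = _h_total_from_nbs(pH, k)
    ta = TA * 1e-6
    carb_alk = ta - _noncarbonate_alkalinity(h, k)
    denom = h * h + k.K1 * h + k.K1 * k.K2
    dic = carb_alk * denom / (k.K1 * h + 2.0 * k.K1 * k.K2)
    if dic <= 0:
        raise CarbonateError(
            f"TA {TA} umol/kg too low to support pH {pH}: no physical DIC"
        )
    co2, hco3, co3 = _speciate(dic, h, k)
    omega = k.CaT * co3 / k.Ksp_calcite
    return CarbonateSystem(
        conditions=conditions, pH=pH, TA=TA,
        DIC=dic * 1e6, CO2=co2 * 1e6, HCO3=hco3 * 1e6, CO3=co3 * 1e6,
        omega_calcite=omega, parameterization=k.parameterization,
    )


def solve_from_dic_ta(
    DIC: float,
    TA: float,
    conditions: SeawaterConditions | None = None,
    constants: ConstantSet | None = None,
) -> CarbonateSystem:
    """Speciate from DIC and TA (both umol/kg) by root-finding on pH.

    The alkalinity residual is strictly monotone in pH, so a bracketed
    Brent search on pH_NBS in [2, 12] either converges or proves the
    pair infeasible.
    """
    for name, v in (("DIC", DIC), ("TA", TA)):
        if not (0.0 < v <= 5000.0):
            raise CarbonateError(f"{name} {v} umol/kg outside (0, 5000]")
    conditions = conditions or SeawaterConditions()
    k = constants or equilibrium_constants(conditions)
    dic = DIC * 1e-6
    ta = TA * 1e-6

    def residual(ph_nbs: float) -> float:
        h = _h_total_from_nbs(ph_nbs, k)
        _, hco3, co3 = _speciate(dic, h, k)
        return hco3 + 2.0 * co3 + _noncarbonate_alkalinity(h, k) - ta

    lo, hi = 2.0, 12.0
    if residual(lo) * residual(hi) > 0:
        raise CarbonateError(
            f"no pH in [2, 12] satisfies DIC={DIC}, TA={TA} umol/kg"
        )
    ph = brentq(residual, lo, hi, xtol=1e-8)
    h = _h_total_from_nbs(ph, k)
    co2, hco3, co3 = _speciate(dic, h, k)
    omega = k.CaT * co3 / k.Ksp_calcite
    return CarbonateSystem(
        conditions=conditions, pH=ph, TA=TA,
        DIC=dic * 1e6, CO2=co2 * 1e6, HCO3=hco3 * 1e6, CO3=co3 * 1e6,
        omega_calcite=omega, parameterization=k.parameterization,
    )


def ta_for_target_ph(current: CarbonateSystem, target_pH: float) -> float:
    """TA change (umol/kg) moving `current` to `target_pH` at constant DIC.

    Negative values are acid additions (HCl), positive are base (NaOH):
    the manipulation used to set culture pH without touching DIC.
    """
    if not (6.0 <= target_pH <= 9.5):
        raise CarbonateError(f"target pH {target_pH} outside [6, 9.5]")
    k = equilibrium_constants(current.conditions)
    h = _h_total_from_nbs(target_pH, k)
    dic = current.DIC * 1e-6
    _, hco3, co3 = _speciate(dic, h, k)
    ta_target = (hco3 + 2.0 * co3 + _noncarbonate_alkalinity(h, k)) * 1e6
    if ta_target <= 0:
        raise CarbonateError(f"target pH {target_pH} infeasible at DIC {current.DIC}")
    return ta_target - current.TA


def omega_calcite(system: CarbonateSystem, constants: ConstantSet) -> float:
    """Calcite saturation state Omega = [Ca++][CO3--]/Ksp."""
    if constants.CaT <= 0:
        raise CarbonateError("CaT must be positive")
    return constants.CaT * (system.CO3 * 1e-6) / constants.Ksp_calcite
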