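"""Independent CO2SYS-equivalent oracle for the carbonate solver tests.

A separate transcription of the same published constant parameterization
(Lueker et al. 2000 K1/K2; Dickson 1990 KB, KS; Dickson & Riley 1979 KF;
Millero 1995 KW; Mucci 1983 calcite Ksp; Weiss 1974 K0; Takahashi 1982
fH) solved by a deliberately different route: everything is expressed as
a total-alkalinity function of free-scale [H+] and solved by bisection —
no linear elimination, no shared code with the package.
"""

from __future__ import annotations

from math import exp, log, log10, sqrt

from scipy.optimize import brentq


def oracle_constants(t_c: float, s: float) -> dict[str, float]:
    tk = t_c + 273.15
    i = 19.924 * s / (1000.0 - 1.005 * s)

    ks = exp(
        -4276.1 / tk + 141.328 - 23.093 * log(tk)
        + (-13856.0 / tk + 324.57 - 47.986 * log(tk)) * sqrt(i)
        + (35474.0 / tk - 771.54 + 114.723 * log(tk)) * i
        - (2698.0 / tk) * i ** 1.5
        + (1776.0 / tk) * i ** 2
        + log(1.0 - 0.001005 * s)
    )
    kf = exp(1590.2 / tk - 12.641 + 1.525 * sqrt(i) + log(1.0 - 0.001005 * s))
    st = 0.14 / 96.062 * s / 1.80655
    ft = 0.000067 / 18.998 * s / 1.80655

    # scale factors relative to free [H+]
    tot = 1.0 + st / ks
    sws = 1.0 + st / ks + ft / kf

    k1_tot = 10.0 ** -(
        3633.86 / tk - 61.2172 + 9.67770 * log(tk) - 0.011555 * s + 0.0001152 * s * s
    )
    k2_tot = 10.0 ** -(
        471.78 / tk + 25.9290 - 3.16967 * log(tk) - 0.01781 * s + 0.0001122 * s * s
    )
    kb_tot = exp(
        (-8966.90 - 2890.53 * sqrt(s) - 77.942 * s + 1.728 * s ** 1.5 - 0.0996 * s * s)
        / tk
        + 148.0248 + 137.1942 * sqrt(s) + 1.62142 * s
        + (-24.4344 - 25.085 * sqrt(s) - 0.2474 * s) * log(tk)
        + 0.053105 * sqrt(s) * tk
    )
    kw_sws = exp(
        148.9802 - 13847.26 / tk - 23.6521 * log(tk)
        + (118.67 / tk - 5.977 + 1.0495 * log(tk)) * sqrt(s)
        - 0.01615 * s
    )
    k0 = exp(
        -60.2409 + 9345.17 / tk + 23.3585 * log(tk / 100.0)
        + s * (0.023517 - 0.00023656 * tk + 0.0047036 * (tk / 100.0) ** 2)
    )
    ksp = 10.0 ** (
        -171.9065 - 0.077993 * tk + 2839.319 / tk + 71.595 * log10(tk)
        + (-0.77712 + 0.0028426 * tk + 178.34 / tk) * sqrt(s)
        - 0.07711 * s
        + 0.0041249 * s ** 1.5
    )
    fh = 1.2948 - 0.002036 * tk + (0.0004607 - 0.000001475 * tk) * s * s

    return {
        # all equilibrium constants re-expressed on the FREE scale
        "k1": k1_tot / tot,
        "k2": k2_tot / tot,
        "kb": kb_tot / tot,
        "kw": kw_sws / sws,
        "ks": ks,
        "kf": kf,
        "k0": k0,
        "ksp": ksp,
        "bt": 0.0004157 * s / 35.0,
        "cat": 0.02128 / 40.087 * s / 1.80655,
        "st": st,
        "ft": ft,
        "fh": fh,
        "sws": sws,
        "tot": tot,
    }


def _ta_of_hfree(hf: float, dic: float, k: dict[str, float]) -> float:
    """Total alkalinity (mol/kg) at free-scale [H+], given DIC (mol/kg)."""
    d = hf * hf + k["k1"] * hf + k["k1"] * k["k2"]
    hco3 = dic * k["k1"] * hf / d
    co3 = dic * k["k1"] * k["k2"] / d
    boh4 = k["bt"] / (1.0 + hf / k["kb"])
    oh = k["kw"] / hf
    hso4 = k["st"] * hf / (k["ks"] + hf)
    hfl = k["ft"] * hf / (k["kf"] + hf)
    return hco3 + 2.0 * co3 + boh4 + oh - hf - hso4 - hfl


def _hfree_from_nbs(ph_nbs: float, k: dict[str, float]) -> float:
    return 10.0 ** (-ph_nbs) / (k["fh"] * k["sws"])


def oracle_from_ph_ta(
    ph_nbs: float, ta_umol: float, t_c: float = 15.0, s: float = 35.0
) -> dict[str, float]:
    """Speciation (umol/kg) from pH_NBS and TA, solving DIC by bisection."""
    k = oracle_constants(t_c, s)
    hf = _hfree_from_nbs(ph_nbs, k)
    ta = ta_umol * 1e-6
    dic = brentq(lambda d: _ta_of_hfree(hf, d, k) - ta, 1e-9, 0.02, xtol=1e-15)
    d = hf * hf + k["k1"] * hf + k["k1"] * k["k2"]
    co2 = dic * hf * hf / d
    hco3 = dic * k["k1"] * hf / d
    co3 = dic * k["k1"] * k["k2"] / d
    return {
        "DIC": dic * 1e6,
        "CO2": co2 * 1e6,
        "HCO3": hco3 * 1e6,
        "CO3": co3 * 1e6,
        "omega": k["cat"] * co3 / k["ksp"],
        "TA": ta_umol,
        "pH": ph_nbs,
    }


def oracle_ph_from_dic_ta(
    dic_umol: float, ta_umol: float, t_c: float = 15.0, s: float = 35.0
) -> float:
    """pH_NBS from DIC and TA by bisection on free [H+]."""
    k = oracle_constants(t_c, s)
    dic, ta = dic_umol * 1e-6, ta_umol * 1e-6
    hf = brentq(
        lambda h: _ta_of_hfree(h, dic, k) - ta, 1e-13, 1e-2, xtol=1e-20, rtol=1e-14
    )
    return -log10(hf * k["fh"] * k["sws"])
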