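"""Culture physiology: growth rates, carbon quotas, production, pH optima.

Converts routine culture observations — cell counts over time and
light-microscope morphometrics — into the quantities that matter for a
calcifier's carbon budget: specific growth rate mu, particulate organic
carbon (POC) quota from biovolume allometry, particulate inorganic
carbon (PIC) quota from coccolith geometry, their daily production
rates, and the PIC/POC ratio.  A quadratic-vertex fit locates the pH
optimum of any of these responses across acclimation treatments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PhysiologyConstants",
    "CountSeries",
    "CellMorphometry",
    "ProductionRates",
    "growth_rate",
    "volume_from_area",
    "poc_quota",
    "coccolith_volume",
    "pic_quota",
    "production_rates",
    "ph_optimum",
]

M_C = 12.011  # g/mol
M_CACO3 = 100.087  # g/mol


class PhysiologyError(ValueError):
    pass


@dataclass(frozen=True)
class PhysiologyConstants:
    """Species- and literature-level constants for quota estimation.

    a, b          : allometric POC = a * V**b for non-diatom protists
                    (pg C per cell, V in um^3)
    ks            : coccolith shape constant, Vc = ks * L**3
                    (0.06 for Coccolithus braarudii)
    rho_calcite   : calcite density, pg/um^3
    """

    a: float = 0.216
    b: float = 0.939
    ks: float = 0.06
    rho_calcite: float = 2.7
    M_C: float = M_C
    M_CaCO3: float = M_CACO3

    def __post_init__(self) -> None:
        if min(self.a, self.ks, self.rho_calcite, self.M_C, self.M_CaCO3) <= 0:
            raise PhysiologyError("all physiological constants must be positive")
        if not (0.5 < self.b < 1.5):
            raise PhysiologyError(f"allometric exponent b={self.b} outside (0.5, 1.5)")
        if not (0.0 < self.ks < 1.0):
            raise PhysiologyError(f"shape constant ks={self.ks} outside (0, 1)")


DEFAULT_CONSTANTS = PhysiologyConstants()


@dataclass(frozen=True)
class CountSeries:
    """Cell counts of one replicate culture.

    times in days (strictly increasing), densities in cells/mL.  Dilute
    batch cultures are held between ~500 and 4000 cells/mL to keep the
    carbonate chemistry stable; densities far outside that are suspect.
    """

    times: tuple[float, ...]
    densities: tuple[float, ...]
    replicate_id: str = ""
    plausible: tuple[float, float] = (100.0, 50_000.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.densities, dtype=float)
        if t.size != d.size or t.size < 2:
            raise PhysiologyError("need matching times/densities with >= 2 points")
        if not np.all(np.diff(t) > 0):
            raise PhysiologyError("times must be strictly increasing")
        if np.any(d <= 0):
            raise PhysiologyError("densities must be positive")
        lo, hi = self.plausible
        if np.any(d < lo) or np.any(d > hi):
            raise PhysiologyError(
                f"density outside plausibility window [{lo}, {hi}] cells/mL"
            )


@dataclass(frozen=True)
class CellMorphometry:
    """Per-cell microscope measurements.

    decalcified_area : um^2 projected area of the naked cell
    coccolith_length : um distal shield length L
    coccolith_count  : coccoliths per cell, discarded ones included
    """

    decalcified_area: float
    coccolith_length: float
    coccolith_count: int
    coccosphere_volume: float | None = None
    cell_id: str = ""

    def __post_init__(self) -> None:
        if self.decalcified_area <= 0 or self.coccolith_length <= 0:
            raise PhysiologyError("areas and lengths must be positive")
        if self.coccolith_count < 1:
            raise PhysiologyError("coccolith count must be >= 1")


@dataclass(frozen=True)
class ProductionRates:
    """Daily per-cell carbon fluxes; quotas in pg C, production in pmol C/d."""

    mu: float
    POC_quota: float
    PIC_quota: float
    POC_production: float
    PIC_production: float
    pic_poc: float | None


def growth_rate(series: CountSeries) -> float:
    """Specific growth rate mu (1/day) from a count time series.

    Least-squares slope of ln(density) against time; with exactly two
    points this reduces to ln(N1/N0)/(t1-t0).
    """
    t = np.asarray(series.times, dtype=float)
    logn = np.log(np.asarray(series.densities, dtype=float))
    slope, _ = np.polyfit(t, logn, 1)
    return float(slope)


def volume_from_area(area: float) -> float:
    """Spherical cell volume (um^3) from projected area (um^2).

    The projected image of a sphere is a disc, so r = sqrt(A/pi) and
    V = (4/3) pi r^3.
    """
    if area <= 0:
        raise PhysiologyError(f"area must be positive, got {area}")
    r = math.sqrt(area / math.pi)
    return 4.0 / 3.0 * math.pi * r ** 3


def poc_quota(volume: float, constants: PhysiologyConstants = DEFAULT_CONSTANTS) -> float:
    """POC quota (pg C/cell) from cell biovolume via POC = a * V**b."""
    if volume <= 0:
        raise PhysiologyError(f"volume must be positive, got {volume}")
    return constants.a * volume ** constants.b


def coccolith_volume(L: float, constants: PhysiologyConstants = DEFAULT_CONSTANTS) -> float:
    """Calcite volume of one coccolith (um^3) from distal shield length L."""
    if L <= 0:
        raise PhysiologyError(f"coccolith length must be positive, got {L}")
    return constants.ks * L ** 3


def pic_quota(
    n: int, L: float, constants: PhysiologyConstants = DEFAULT_CONSTANTS
) -> float:
    """PIC quota (pg C/cell): n coccoliths of pure calcite.

    PIC = n * ks L^3 * rho * (M_C / M_CaCO3); the molar-mass ratio
    converts calcite mass to carbon mass.
    """
    if n < 1:
        raise PhysiologyError(f"coccolith count must be >= 1, got {n}")
    vc = coccolith_volume(L, constants)
    return n * vc * constants.rho_calcite * (constants.M_C / constants.M_CaCO3)


def production_rates(
    mu: float,
    POC_quota: float,
    PIC_quota: float,
    constants: PhysiologyConstants = DEFAULT_CONSTANTS,
) -> ProductionRates:
    """Daily production (pmol C/cell/day) = quota [pmol C] * mu [1/day]."""
    if mu < 0:
        raise PhysiologyError(f"growth rate must be non-negative, got {mu}")
    if POC_quota < 0 or PIC_quota < 0:
        raise PhysiologyError("quotas must be non-negative")
    poc_prod = POC_quota / constants.M_C * mu
    pic_prod = PIC_quota / constants.M_C * mu
    ratio = pic_prod / poc_prod if poc_prod > 0 else None
    return ProductionRates(
        mu=mu, POC_quota=POC_quota, PIC_quota=PIC_quota,
        POC_production=poc_prod, PIC_production=pic_prod, pic_poc=ratio,
    )


def _vertex(ph: np.ndarray, resp: np.ndarray) -> float:
    b2, b1, _ = np.polyfit(ph, resp, 2)
    if b2 >= 0 or not np.isfinite(b2):
        raise PhysiologyError("quadratic fit is not concave: no pH optimum")
    return float(-b1 / (2.0 * b2))


def ph_optimum(
    ph_values: Sequence[float],
    responses: Sequence[float] | Sequence[Sequence[float]],
    n_experiments: int | None = None,
) -> tuple[float, float | None]:
    """pH optimum as the vertex of a concave quadratic fit.

    ``responses`` is either one response per pH (a single experiment;
    SE is then None) or one sequence per experiment, each parallel to
    ``ph_values``.  With multiple experiments the vertex is fitted per
    experiment and the optimum reported as mean +/- SD/sqrt(n).
    """
    ph = np.asarray(ph_values, dtype=float)
    if np.unique(ph).size < 3:
        raise PhysiologyError("need >= 3 distinct pH values for a quadratic fit")
    resp = np.asarray(responses, dtype=float)
    if resp.ndim == 1:
        if resp.size != ph.size:
            raise PhysiologyError("responses must parallel ph_values")
        return _vertex(ph, resp), None
    if resp.shape[1] != ph.size:
        raise PhysiologyError("each experiment must parallel ph_values")
    vertices = np.array([_vertex(ph, row) for row in resp])
    n = n_experiments or len(vertices)
    se = float(np.std(vertices, ddof=1) / math.sqrt(n)) if n > 1 else None
    return float(np.mean(vertices)), se
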