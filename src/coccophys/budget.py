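"""Net cellular H+ budget from calcification and photosynthesis.

Calcification precipitates CaCO3 from Ca++ and DIC and is a net proton
source; photosynthetic carbon fixation is a proton sink only when the
carbon enters as HCO3-.  The stoichiometry therefore depends on which
DIC species the cell takes up:

* HCO3- only : 1 H+ consumed per C fixed, 1 H+ generated per C
  precipitated, so H_net = PIC_prod - POC_prod.
* CO2 only   : photosynthesis is H+-neutral and calcification generates
  2 H+ per C precipitated, so H_net = 2 * PIC_prod.

Real cells use a mixture, so the two scenarios bound the achievable net
H+ load; ``h_budget_envelope`` returns that band and ``h_budget`` also
accepts a CO2-uptake fraction interpolating between them.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .physiology import ProductionRates

__all__ = ["Scenario", "ProtonBudget", "h_budget", "h_budget_envelope"]


class Scenario(str, Enum):
    HCO3_only = "HCO3_only"
    CO2_only = "CO2_only"


@dataclass(frozen=True)
class ProtonBudget:
    """Net H+ load, pmol H+/cell/day, with its two components."""

    scenario: str
    H_net: float
    H_from_calcification: float
    H_from_photosynthesis: float


class BudgetError(ValueError):
    pass


def _check(rates: ProductionRates) -> None:
    if rates.PIC_production < 0 or rates.POC_production < 0:
        raise BudgetError("production rates must be non-negative")


def h_budget(
    rates: ProductionRates,
    scenario: Scenario | str | None = None,
    f_co2: float | None = None,
) -> ProtonBudget:
    """Net H+ production for one DIC-uptake scenario.

    Either name a scenario or give ``f_co2``, the fraction of carbon
    taken up as CO2, which interpolates linearly between the HCO3--only
    (f_co2=0) and CO2-only (f_co2=1) stoichiometries.
    """
    _check(rates)
    pic, poc = rates.PIC_production, rates.POC_production
    if f_co2 is not None:
        if scenario is not None:
            raise BudgetError("give either a scenario or f_co2, not both")
        if not (0.0 <= f_co2 <= 1.0):
            raise BudgetError(f"f_co2 {f_co2} outside [0, 1]")
        calc = (1.0 + f_co2) * pic
        photo = -(1.0 - f_co2) * poc
        label = f"mixed(f_co2={f_co2:g})"
    else:
        try:
            scenario = Scenario(scenario)
        except ValueError:
            raise BudgetError(f"unknown scenario {scenario!r}") from None
        if scenario is Scenario.HCO3_only:
            calc, photo, label = pic, -poc, scenario.value
        else:
            calc, photo, label = 2.0 * pic, 0.0, scenario.value
    return ProtonBudget(
        scenario=label,
        H_net=calc + photo,
        H_from_calcification=calc,
        H_from_photosynthesis=photo,
    )


def h_budget_envelope(rates: ProductionRates) -> tuple[float, float]:
    """(low, high) bounds on the net H+ load, pmol H+/cell/day.

    Low is the HCO3--only budget, high the CO2-only budget; their gap is
    exactly PIC_production + POC_production.
    """
    _check(rates)
    low = h_budget(rates, Scenario.HCO3_only).H_net
    high = h_budget(rates, Scenario.CO2_only).H_net
    return low, high
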