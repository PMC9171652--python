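# coccophys

A tested Python pipeline for the acid-base physiology of calcifying
phytoplankton, built around the heavily calcified coccolithophore
*Coccolithus braarudii* under ocean-acidification conditions.

Intracellular calcification makes a coccolithophore cell a net proton
source: each mole of CaCO₃ precipitated generates H⁺ that must leave
the cell, and whether photosynthesis offsets any of it depends on
whether carbon enters as HCO₃⁻ or CO₂.  Passive H⁺ efflux through
voltage-gated H⁺ (Hv) channels is only possible while the outward
proton motive force across the plasma membrane is positive — and that
pmf collapses as seawater acidifies.  `coccophys` implements every
quantitative step of that argument:

* **Carbonate chemistry** (`coccophys.carbonate`) — full CO₂-system
  speciation from (pH_NBS, TA) or (DIC, TA), calcite saturation state
  Ω = [Ca²⁺][CO₃²⁻]/Ksp, and the TA-manipulation-at-constant-DIC used
  to set culture pH.  One documented constant parameterization (Lueker
  2000 / Dickson 1990 / Millero 1995 / Mucci 1983).
* **Growth & carbon production** (`coccophys.physiology`) — µ from
  ln-linear count fits; POC = a·V^b (a = 0.216, b = 0.939) from
  decalcified-cell biovolume; PIC = n·ks·L³·ρ·(M_C/M_CaCO₃) with
  ks = 0.06 and ρ = 2.7 pg/µm³; production = quota × µ; quadratic-vertex
  pH optima with experiment-level SE.
* **Cellular H⁺ budget** (`coccophys.budget`) — net H⁺ load between the
  HCO₃⁻-only (PIC − POC) and CO₂-only (2·PIC) end members.
* **Membrane energetics** (`coccophys.membrane`) —
  pmf = V_m − E_H with E_H = (2.303RT/F)(pH_cyt − pH_o), its envelope
  over measured pH_cyt and V_m bounds, and its zero crossing in pH_o.
* **Voltage clamp** (`coccophys.ephys`) — linear leak subtraction, late
  window I–V in pA/pF, the <2.5 pA/pF at +45 mV deficiency
  classification, tail-current reversal potentials, series-resistance
  QC.
* **Cytosolic pH** (`coccophys.snarf`) — SNARF-1 ratiometric
  calibration pH = 0.8205·ln(F630/F580) + 7.1101, drift QC, per-phase
  responses, the Δ[H⁺] efflux statistic and defective-efflux
  classification, two-sample KS population comparisons.
* **Expression** (`coccophys.qpcr`) — efficiency-corrected ΔΔCt
  normalized to the geometric mean of two reference genes.
* **Synthetic data** (`coccophys.synth`) — seeded generators for every
  input type, emitting ground truth, so the whole chain is testable
  offline.

The repository is organised as an analysis project: the numbered
scripts under `analysis/` walk through the acclimation experiment
(carbonate conditions → production → H⁺ budget → pmf → patch clamp →
cytosolic pH → expression) and write their tables to `results/`; all
computation lives in the library under `src/`.

## Worked example

```python
from coccophys import (solve_from_ph_ta, ta_for_target_ph, pic_quota,
                       poc_quota, production_rates, h_budget_envelope,
                       pmf_zero_ph, volume_from_area)

ctrl = solve_from_ph_ta(pH=8.15, TA=2450.0)      # control seawater, 15 degC
print(f"DIC {ctrl.DIC:.0f} umol/kg, CO2 {ctrl.CO2:.1f}, omega {ctrl.omega_calcite:.2f}")
print(f"to pH 7.55: add {ta_for_target_ph(ctrl, 7.55):.0f} umol/kg TA (acid)")

poc = poc_quota(volume_from_area(200.0))          # 200 um^2 decalcified cell
pic = pic_quota(n=48, L=8.0)                      # 48 coccoliths, 8 um shields
rates = production_rates(0.55, poc, pic)
low, high = h_budget_envelope(rates)
print(f"POC {poc:.0f} pg, PIC {pic:.0f} pg, PIC/POC {rates.pic_poc:.2f}")
print(f"net H+ load {low:.1f} (HCO3- only) to {high:.1f} (CO2 only) pmol/cell/d")
print(f"pmf zero crossing: pH_o {pmf_zero_ph(6.8, -46.0, 15.0):.2f}")
```

prints

```
DIC 2228 umol/kg, CO2 16.5, omega 3.93
to pH 7.55: add -226 umol/kg TA (acid)
POC 288 pg, PIC 478 pg, PIC/POC 1.66
net H+ load 8.7 (HCO3- only) to 43.8 (CO2 only) pmol/cell/d
pmf zero crossing: pH_o 7.60
```

Read: the control culture holds 2228 µmol/kg DIC and is calcite-
supersaturated; acidifying it to pH 7.55 takes ~226 µmol/kg of strong
acid.  A typical cell fixes carbon into calcite ~1.7× faster than into
biomass, so it must export 9–44 pmol H⁺/day depending on its carbon
source — and the outward driving force that Hv channels need to do this
passively vanishes once seawater drops to pH ≈ 7.6, right at the most
acidified treatment.

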