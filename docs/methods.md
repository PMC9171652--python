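# Methods

`coccophys` implements the quantitative chain of a coccolithophore
acid-base physiology study as a reusable, tested pipeline: seawater
carbonate chemistry → growth and PIC/POC production → net cellular H⁺
budget → plasma-membrane proton electrochemistry → single-cell
measurements of the H⁺-efflux machinery (voltage clamp, ratiometric
cytosolic pH) → Hv-channel gene expression.  This note records the
models, the parameters that matter, and the design choices made where
the underlying methods left them open.

## Carbonate system (`coccophys.carbonate`)

The CO₂ system is solved from the measured pair (pH_NBS, TA) or
(DIC, TA).  Equilibrium constants use one fixed parameterization —
Lueker et al. (2000) K1/K2, Dickson (1990) KB and KS, Dickson & Riley
(1979) KF, Millero (1995) KW, Weiss (1974) K0, Mucci (1983) calcite
Ksp — with borate, calcium, sulfate and fluoride totals scaled from
salinity.  The alkalinity expression includes the carbonate, borate,
water, bisulfate and HF terms; nutrient alkalinity is out of scope
(culture media, not titration processing).

Numerical choices:

* Internal proton scale is the **total scale**; bench pH meters report
  NBS, bridged via the Takahashi et al. (1982) activity coefficient fH
  and the sulfate/fluoride speciation factors.  The conversion is an
  approximation inherent to the NBS scale itself (~0.13 pH units at
  S = 35), identical to common CO2-system calculators.
* From (pH, TA), DIC follows **linearly** (every non-carbonate
  alkalinity term is fixed by pH); from (DIC, TA), pH is found by
  bracketed Brent iteration on pH ∈ [2, 12] with 1e-8 tolerance — the
  residual is monotone, so convergence is guaranteed or the pair is
  reported infeasible.
* Defaults: 15 °C (culture temperature), salinity 35, surface pressure.
  The experimental pH manipulation is modelled as a TA change at
  constant DIC (`ta_for_target_ph`), i.e. strong acid/base addition in
  a sealed, headspace-free bottle.

The test oracle is a second, independently transcribed solver (same
published constant formulas, different algebra and root variable) plus
the standard 25 °C/S 35 check values for each constant.

## Quotas and production (`coccophys.physiology`)

* Growth rate: least-squares slope of ln(density) vs time; equivalent
  to ln(N₁/N₀)/Δt for two points.  Count series are validated against
  the dilute-batch window (~500–4000 cells/mL).
* POC quota: the non-diatom protist allometry POC = a·V^b with
  a = 0.216 pg·µm⁻³ᵇ, b = 0.939.  Cell volume comes from the projected
  area of decalcified cells assuming sphericity, r = √(A/π) — projected
  area is what a microscope image gives.
* PIC quota: PIC = n · ks·L³ · ρ · (M_C/M_CaCO₃) with the
  *C. braarudii* shape constant ks = 0.06, calcite density
  ρ = 2.7 pg/µm³, and n the coccolith count per cell **including
  discarded coccoliths**.
* Production = quota [pmol C, via M_C = 12.011] × µ [d⁻¹].
* pH optima: vertex −β₁/(2β₂) of an unweighted second-order polynomial
  fit per independent experiment; the reported optimum is the mean of
  experiment-level vertices with SE = SD/√n.  Convex or degenerate fits
  raise rather than returning an extrapolated vertex.

## H⁺ budget (`coccophys.budget`)

Only calcification (H⁺ source) and photosynthesis (H⁺ sink when carbon
enters as HCO₃⁻) are counted; they dominate the budget.  End members:
HCO₃⁻-only uptake gives H_net = PIC_prod − POC_prod; CO₂-only gives
H_net = 2·PIC_prod.  The envelope between them has width exactly
PIC_prod + POC_prod, and an optional CO₂-uptake fraction f_CO2 ∈ [0, 1]
interpolates linearly.  No default f_CO2 is asserted — the mixture is
condition-dependent — so results are reported as envelopes.

## Membrane energetics (`coccophys.membrane`)

pmf = −(2.303RT/F)·ΔpH + V_m with ΔpH = pH_cyt − pH_o, so
pmf = V_m − E_H and positive values drive H⁺ outward.  (The sign of
ΔpH is the one convention that reproduces the observed behaviour:
outward pmf at seawater pH 8.15, zero crossing near 7.6.)  z = 1 is
fixed.  The envelope uses the measured corner values pH_cyt ∈
{6.8, 7.1} and V_m ∈ {−46, −28} mV at 15 °C; the four corner zero
crossings fall in [7.29, 7.90].  The Hv activation potential is
modelled as E_H plus a user offset — gating kinetics are out of scope.

## Voltage clamp (`coccophys.ephys`)

Sign convention: outward positive.  Leak subtraction is ohmic,
(V_step − holding)/R_seal with the pretest seal resistance.  The I–V
value per step is the signed extremum over the window from 500 ms to
the step end (the outward conductance activates slowly, so the late
extremum approximates steady state), normalized by Cm to pA/pF.  A
cell is **defective** iff the density at +45 mV is < 2.5 pA/pF
(strictly); +45 mV lies 5 mV above the −80…+40 mV protocol, so the
density there is linearly extrapolated from the top segment, with
extrapolation capped at 10 mV.  Tail-current reversal potentials are
the x-intercept of a least-squares line through peak tail currents
(signed extremum within 20 ms of the tail step after a 2-ms capacitive
blank).  Recordings whose series resistance varies by more than 15% of
its initial value are rejected.

## Cytosolic pH (`coccophys.snarf`)

Calibration: pH_cyt = 0.8205·ln(F630/F580) + 7.1101 (in vitro SNARF-1
fit).  Background subtraction is omitted (background was minimal in the
source protocol).  Per-phase statistics use the mean of the final 30 s
of each perfusion phase — plateaus are reached within seconds, and the
source protocol states no window.  Drift QC compares the flanking
reference-pH (8.15) phases and discards traces whose pH offset exceeds
4% of the starting pH; the criterion is applied on pH units, the most
literal reading of a "pH_cyt offset", and is configurable.

The efflux statistic is Δ[H⁺] = 10^(−pH_acid) − 10^(−pH_return) on
transfer from external pH 6.5 back to 8.15 (positive = net efflux).
Cells with Δ[H⁺] < 20 pM are classified efflux-defective.  Note the
unit tension: cytosolic [H⁺] near pH 6.85 is ~140 nM, so a 20 pM
criterion is ~10⁻⁴ pH units — far below measurement noise — whereas
observed responsive cells move hundreds of nM.  The printed value is
kept as the default because any threshold below the gap between the
response modes (~15 nM vs ~300 nM in the generator; the same gap
structure appears in the real histograms) yields the same
classification; the threshold is a parameter throughout, and the
population tests use an explicit mode-separating value (50 nM).
Population comparisons use the two-sided two-sample KS test.

## qPCR (`coccophys.qpcr`)

Efficiency-corrected ddCt: technical replicates are averaged on the Ct
scale (standard practice), then
ratio = E_t^(ΔCt_t) / geomean_r(E_r^(ΔCt_r)) over ≥ 2 endogenous
reference genes, relative to a calibrator sample.  Amplification
efficiencies are inputs; a helper converts dilution-series slopes
(E = 10^(−1/slope)).  Reference-gene stability scoring (geNorm) is out
of scope.

## Synthetic data (`coccophys.synth`)

The generators define the study conditions the pipeline is tested
under; they are deterministic per seed and emit ground truth.

* **Cultures**: exponential growth (default µ = 0.55 d⁻¹, within the
  species' 0.45–0.6 range) from 500 cells/mL with 5% lognormal count
  noise, counted daily for 3 d — staying inside the 500–4000 cells/mL
  window.
* **Morphometrics**: lognormal areas (median 200 µm², CV 15%) and
  coccolith lengths (median 8 µm, CV 8%), Poisson coccolith counts
  (mean 48 per cell including discarded).  These defaults put POC near
  300 pg C/cell and PIC/POC near 1.6, the heavily calcified phenotype
  at the pH optimum.
* **SNARF traces**: 15-min schedules (reference 8.15 → acid 6.5 →
  reference 8.15, 5 min each) sampled at 3.3 Hz; responsive cells relax
  first-order (τ = 5 s) to plateaus with gain 0.30 pH_cyt per pH_o
  unit around baseline 6.85, defective cells with gain 0.01; 1%
  multiplicative fluorescence noise; optional imposed terminal drift
  for QC testing.
* **Current families**: ohmic leak (1 GΩ) + outward conductance with
  Boltzmann activation 20 mV above the configured reversal potential
  (slope 8 mV, τ_act = 100 ms) + optional early inward Cl⁻-like
  transient + additive Gaussian noise; a helper reproduces the exact
  density the classifier will see at +45 mV, so the classification flip
  point can be checked against generator arithmetic.
* **qPCR plates**: Ct values implied by configured fold changes and
  efficiencies plus Gaussian Ct noise.

What the generators do **not** emulate: diel cell-cycle structure in
counts and volumes, dye loading/leakage artefacts, capacitance
transients and voltage-dependent gating kinetics beyond first-order
activation, inter-gene efficiency differences within a plate, and any
covariance between a cell's calcification state and its channel
activity.  Passing tests therefore demonstrate that the analysis chain
recovers known inputs under the stated noise models — not that those
models exhaust real measurement pathology.

## Problem sizes

The analysis scripts use 3 experiments × 3 replicates × 5 pH levels for
growth, 25–30 cells per morphometric sample, 36–61 SNARF cells per
treatment (matching the reported group sizes), 18 patched cells per
treatment, and 200 seeded replicates for the optimum-recovery
simulation — sizes chosen to mirror the study design while keeping the
full suite fast.

## Known limitations

* The NBS↔total scale bridge (fH) is itself an approximation; all
  comparisons are made with a consistently parameterized oracle, not
  against titration data.
* The paper-level constants (a, b, ks, ρ) carry their published
  uncertainties; no error propagation through the allometric relations
  is attempted.
* The pmf model is thermodynamic only — no surface-potential or
  ionic-strength corrections and no channel kinetics.
* `ph_optimum` requires concavity; flat or monotone responses
  deliberately error instead of reporting an out-of-range vertex.
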