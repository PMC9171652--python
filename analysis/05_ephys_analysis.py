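#!/usr/bin/env python
"""Whole-cell H+ current analysis across acclimation treatments.

Simulates voltage-clamp families for cells from three acclimation
treatments, with the fraction of current-deficient cells and the mean
conductance amplitude degraded in the pH 7.55 treatment; runs the full
analysis chain (leak subtraction, I-V extraction, pA/pF normalization,
<2.5 pA/pF at +45 mV classification) and recovers tail-current reversal
potentials against the generator's configured values.

Writes results/ephys_classification.csv and results/ephys_reversal.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from coccophys import (
    classify_outward,
    iv_curve,
    leak_subtract,
    nernst_eh,
    tail_reversal_potential,
)
from coccophys.ephys import density_at, tail_peaks_from_sweeps
from coccophys.membrane import MembraneState
from coccophys.synth import EphysConfig, gen_current_family, gen_tail_family

SEED = 1
N_CELLS = 18  # cells per treatment
# fraction of cells with lost Hv conductance, and healthy-cell conductance
TREATMENTS = {7.55: (0.5, 1.2), 8.15: (0.05, 2.0), 8.75: (0.1, 1.8)}

out_dir = Path("results")
out_dir.mkdir(exist_ok=True)

rng = np.random.default_rng(SEED)
rows = []
for ph, (f_deficient, g_healthy) in TREATMENTS.items():
    e_h = nernst_eh(MembraneState(6.85, ph, -46.0, 15.0))
    for cell in range(N_CELLS):
        deficient = rng.random() < f_deficient
        g = 0.05 if deficient else g_healthy * float(rng.lognormal(0.0, 0.2))
        cfg = EphysConfig(g_out=g, E_rev=float(e_h), noise_sd=2.0)
        rec = gen_current_family(cfg, int(rng.integers(2**31)))
        iv = iv_curve(leak_subtract(rec))
        rows.append(
            {
                "acclimation_pH": ph,
                "cell": cell + 1,
                "density_45mV_pA_pF": round(density_at(iv, 45.0), 2),
                "classification": classify_outward(iv),
                "truth_deficient": deficient,
            }
        )

cells = pd.DataFrame(rows)
cells.to_csv(out_dir / "ephys_classification.csv", index=False)

frac = (
    cells.assign(defective=cells.classification == "defective")
    .groupby("acclimation_pH")["defective"]
    .mean()
)
print("Fraction of cells without an outward current (<2.5 pA/pF at +45 mV):")
print((100 * frac).round(1).to_string())

# tail-current reversal potentials track E_H in every treatment
rev_rows = []
for ph in TREATMENTS:
    e_h = float(nernst_eh(MembraneState(6.85, ph, -46.0, 15.0)))
    cfg = EphysConfig(g_out=2.0, E_rev=e_h, noise_sd=1.0)
    sweeps, levels, start = gen_tail_family(cfg, seed=SEED)
    e_rev = tail_reversal_potential(
        tail_peaks_from_sweeps(sweeps, levels, cfg.sample_interval, start)
    )
    rev_rows.append(
        {"acclimation_pH": ph, "E_H_mV": round(e_h, 1), "E_rev_mV": round(e_rev, 1)}
    )
rev = pd.DataFrame(rev_rows)
rev.to_csv(out_dir / "ephys_reversal.csv", index=False)
print("\nTail-current reversal potentials vs the H+ equilibrium potential:")
print(rev.to_string(index=False))
print(
    "\nE_rev tracks E_H in all treatments (H+ is the charge carrier); the "
    "current-deficient fraction is concentrated in the pH 7.55 acclimation."
)
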