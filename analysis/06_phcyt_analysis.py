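#!/usr/bin/env python
"""Cytosolic pH regulation and the Delta[H+] efflux statistic.

Simulates SNARF-1 perfusion experiments for three acclimation
treatments — cells are driven to external pH 6.5 and returned to 8.15,
and the drop in cytosolic [H+] on return (Delta[H+]) measures H+ efflux
capacity.  The pH 7.55 treatment contains a defective-efflux
subpopulation; the pipeline applies drift QC, computes per-cell
Delta[H+], classifies cells against a mode-separating threshold, and
compares treatment distributions with two-sample KS tests.

Writes results/efflux_classification.csv and results/ks_tests.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from coccophys import classify_efflux, compare_distributions, delta_h, drift_qc
from coccophys.synth import SnarfConfig, gen_snarf_traces

SEED = 1
# (n cells, defective fraction) per acclimation treatment
TREATMENTS = {7.55: (55, 0.5), 8.15: (61, 0.03), 8.75: (36, 0.05)}
MODE_THRESHOLD = 50e-9  # between the generated response modes (~15 vs ~300 nM)

out_dir = Path("results")
out_dir.mkdir(exist_ok=True)

rows = []
deltas = {}
for i, (ph, (n, f_def)) in enumerate(TREATMENTS.items()):
    cfg = SnarfConfig(n_cells=n, f_defective=f_def)
    traces, labels = gen_snarf_traces(cfg, SEED + i)
    kept = [tr for tr in traces if drift_qc(tr)]
    d = np.array([delta_h(tr) for tr in kept])
    deltas[ph] = d
    for tr, dh in zip(kept, d):
        rows.append(
            {
                "acclimation_pH": ph,
                "cell_id": tr.cell_id,
                "delta_H_nM": round(dh * 1e9, 2),
                "classification": classify_efflux(dh, MODE_THRESHOLD),
            }
        )

cells = pd.DataFrame(rows)
cells.to_csv(out_dir / "efflux_classification.csv", index=False)

frac = (
    cells.assign(defective=cells.classification == "defective")
    .groupby("acclimation_pH")["defective"]
    .mean()
)
print("Fraction of cells with defective H+ efflux:")
print((100 * frac).round(1).to_string())

ks = {}
for a, b in ((7.55, 8.15), (7.55, 8.75), (8.15, 8.75)):
    d_stat, p = compare_distributions(deltas[a], deltas[b])
    ks[f"pH{a}_vs_pH{b}"] = {"D": round(d_stat, 3), "p": float(f"{p:.3g}")}
(out_dir / "ks_tests.json").write_text(json.dumps(ks, indent=2) + "\n")

print("\nTwo-sample KS tests on the Delta[H+] distributions:")
for k, v in ks.items():
    print(f"  {k}: D={v['D']}, p={v['p']}")
print(
    "\nThe pH 7.55 population is bimodal — a large defective-efflux "
    "subpopulation — and differs significantly from both higher-pH "
    "treatments; those two do not differ from each other."
)
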