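#!/usr/bin/env python
"""Growth, carbon quotas and production across the acclimation pH range.

Simulates the acclimation experiment (three independent experiments of
triplicate cultures at five pH levels), derives growth rates from the
count series, POC quotas from decalcified-cell biovolume, PIC quotas
from coccolith counts and lengths, and daily production rates.  The
synthetic response surfaces are concave in pH — growth peaking at pH
8.32, calcification falling off sharply below pH 7.85 — mimicking the
phenotype of a heavily calcified coccolithophore.

Writes results/production_rates.csv and results/ph_optima.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from coccophys import (
    growth_rate,
    ph_optimum,
    pic_quota,
    poc_quota,
    production_rates,
    volume_from_area,
)
from coccophys.synth import (
    CultureConfig,
    MorphometryConfig,
    gen_culture,
    gen_morphometrics,
)

SEED = 1
PH_LEVELS = (7.55, 7.85, 8.15, 8.45, 8.75)

# synthetic acclimation phenotype: quadratic growth response (vertex 8.32)
# and coccolith output collapsing at low pH (count and length reduced)
GROWTH_OPTIMUM = 8.32
MU_MAX = 0.60
COCCOLITHS = {7.55: 42.0, 7.85: 43.0, 8.15: 48.0, 8.45: 52.0, 8.75: 46.0}
LENGTH_UM = {7.55: 7.2, 7.85: 7.8, 8.15: 8.0, 8.45: 8.1, 8.75: 7.9}

out_dir = Path("results")
out_dir.mkdir(exist_ok=True)

rows = []
growth_by_experiment = []
for exp in range(3):
    mus_at_ph = []
    for i, ph in enumerate(PH_LEVELS):
        mu_true = MU_MAX * (1.0 - ((ph - GROWTH_OPTIMUM) / 1.6) ** 2)
        cfg = CultureConfig(mu=mu_true, count_cv=0.03, n_replicates=3)
        series = gen_culture(cfg, SEED + 100 * exp + i)
        cells = gen_morphometrics(
            MorphometryConfig(
                median_area=200.0,
                median_length=LENGTH_UM[ph],
                mean_coccolith_count=COCCOLITHS[ph],
                n_cells=30,
            ),
            SEED + 100 * exp + 50 + i,
        )
        poc = float(
            np.mean([poc_quota(volume_from_area(c.decalcified_area)) for c in cells])
        )
        pic = float(
            np.mean([pic_quota(c.coccolith_count, c.coccolith_length) for c in cells])
        )
        for s in series:
            mu = growth_rate(s)
            r = production_rates(max(mu, 0.0), poc, pic)
            rows.append(
                {
                    "experiment": exp + 1,
                    "replicate_id": s.replicate_id,
                    "pH_NBS": ph,
                    "mu_per_day": round(mu, 4),
                    "POC_pg_cell": round(poc, 1),
                    "PIC_pg_cell": round(pic, 1),
                    "POC_pmol_cell_day": round(r.POC_production, 3),
                    "PIC_pmol_cell_day": round(r.PIC_production, 3),
                    "pic_poc": round(r.pic_poc, 3) if r.pic_poc else None,
                }
            )
        mus_at_ph.append(float(np.mean([growth_rate(s) for s in series])))
    growth_by_experiment.append(mus_at_ph)

df = pd.DataFrame(rows)
df.to_csv(out_dir / "production_rates.csv", index=False)

opt, se = ph_optimum(PH_LEVELS, growth_by_experiment, n_experiments=3)
optima = {"growth": {"optimum_pH": round(opt, 3), "se": round(se, 4)}}
(out_dir / "ph_optima.json").write_text(json.dumps(optima, indent=2) + "\n")

summary = df.groupby("pH_NBS")[["mu_per_day", "POC_pmol_cell_day",
                                "PIC_pmol_cell_day", "pic_poc"]].mean().round(3)
print(summary.to_string())
print(
    f"\nGrowth pH optimum recovered from the count series: "
    f"{opt:.3f} +/- {se:.3f} (configured vertex {GROWTH_OPTIMUM})"
)
print(
    "PIC/POC is lowest in the most acidified treatment: calcification "
    "declines faster than photosynthesis below pH 7.85."
)
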