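"""Efficiency-corrected relative qPCR expression (Pfaffl-style ddCt).

Each target gene's expression, relative to a calibrator sample, is the
efficiency-corrected ratio E_target**(Ct_cal - Ct_sample) divided by the
geometric mean of the same quantity over >= 2 endogenous reference
genes.  Technical replicates are averaged on the Ct scale first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["validate_plate", "relative_expression", "efficiency_from_dilution_slope"]

REQUIRED_COLUMNS = ("sample_id", "gene_id", "role", "Ct", "efficiency")


class QPCRError(ValueError):
    pass


def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format plate table and return it with mean-Ct rows.

    Expects columns sample_id, gene_id, role ('target'/'reference'),
    Ct (cycles), efficiency (amplification factor per cycle, ~2).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in plate.columns]
    if missing:
        raise QPCRError(f"plate table missing columns {missing}")
    bad_roles = set(plate["role"]) - {"target", "reference"}
    if bad_roles:
        raise QPCRError(f"unknown roles {sorted(bad_roles)}")
    if ((plate["Ct"] <= 0) | (plate["Ct"] >= 45)).any():
        raise QPCRError("Ct values must lie in (0, 45)")
    if ((plate["efficiency"] <= 1.5) | (plate["efficiency"] >= 2.2)).any():
        raise QPCRError("efficiencies must lie in (1.5, 2.2)")
    # technical replicates -> mean Ct per sample x gene
    agg = (
        plate.groupby(["sample_id", "gene_id", "role"], as_index=False)
        .agg(Ct=("Ct", "mean"), efficiency=("efficiency", "first"))
    )
    n_refs = (
        agg[agg["role"] == "reference"].groupby("sample_id")["gene_id"].nunique()
    )
    if (n_refs < 2).any() or set(agg["sample_id"]) - set(n_refs.index):
        raise QPCRError("every sample needs >= 2 reference genes")
    return agg


def relative_expression(plate: pd.DataFrame, calibrator_sample: str) -> pd.DataFrame:
    """Per-sample, per-target expression ratio relative to the calibrator.

    ratio = E_t**(Ct_cal,t - Ct_s,t) / geomean_r( E_r**(Ct_cal,r - Ct_s,r) )

    Returns a tidy frame (sample_id, gene_id, ratio, is_calibrator).
    """
    agg = validate_plate(plate)
    if calibrator_sample not in set(agg["sample_id"]):
        raise QPCRError(f"calibrator sample {calibrator_sample!r} not on the plate")
    cal = agg[agg["sample_id"] == calibrator_sample].set_index("gene_id")

    rows = []
    for sample_id, grp in agg.groupby("sample_id"):
        grp = grp.set_index("gene_id")
        missing = set(cal.index) - set(grp.index)
        if missing:
            raise QPCRError(f"sample {sample_id!r} missing genes {sorted(missing)}")
        ref_factors = []
        for gene in cal.index[cal["role"] == "reference"]:
            e = grp.loc[gene, "efficiency"]
            ref_factors.append(e ** (cal.loc[gene, "Ct"] - grp.loc[gene, "Ct"]))
        norm = float(np.exp(np.mean(np.log(ref_factors))))
        for gene in cal.index[cal["role"] == "target"]:
            e = grp.loc[gene, "efficiency"]
            target = e ** (cal.loc[gene, "Ct"] - grp.loc[gene, "Ct"])
            rows.append(
                {
                    "sample_id": sample_id,
                    "gene_id": gene,
                    "ratio": target / norm,
                    "is_calibrator": sample_id == calibrator_sample,
                }
            )
    return pd.DataFrame(rows)


def efficiency_from_dilution_slope(slope: float) -> float:
    """Amplification factor per cycle from a dilution-series Ct slope.

    For Ct vs log10(template), E = 10**(-1/slope); a perfect doubling
    assay gives slope -3.32 and E = 2.
    """
    if slope >= 0:
        raise QPCRError("dilution-series slope must be negative")
    return 10.0 ** (-1.0 / slope)
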