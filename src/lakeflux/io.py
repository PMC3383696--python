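"""CSV interfaces: lake tables, budget tables and fatty-acid profiles."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .fatty_acid_mixing import FattyAcidProfile
from .mass_balance import DAYS_PER_YEAR, LakeHydrology, budget_for_lake, SIGMA_TDOC

LAKE_TABLE_COLUMNS = ["lake_id", "qs_L_m2_d", "mean_depth_m", "hrt_yr", "doc_in_mg_L", "tp_ug_L"]


def read_lake_table(path) -> pd.DataFrame:
    """Read a lake CSV (header required; any one of depth/HRT may be blank)."""
    df = pd.read_csv(path)
    missing = [c for c in LAKE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"lake table missing columns: {missing}")
    return df


def hydrology_from_row(row) -> LakeHydrology:
    depth = row["mean_depth_m"]
    hrt_yr = row["hrt_yr"]
    return LakeHydrology.from_components(
        qs=None if pd.isna(row["qs_L_m2_d"]) else float(row["qs_L_m2_d"]),
        mean_depth=None if pd.isna(depth) else float(depth),
        hrt_years=None if pd.isna(hrt_yr) else float(hrt_yr),
    )


def budgets_from_table(df: pd.DataFrame, sigma: float = SIGMA_TDOC) -> pd.DataFrame:
    """Evaluate the CSTR t-DOC budget for each lake row; one row per lake."""
    rows = []
    for _, row in df.iterrows():
        hyd = hydrology_from_row(row)
        b = budget_for_lake(hyd, float(row["doc_in_mg_L"]), sigma=sigma)
        rows.append(
            {
                "lake_id": row["lake_id"],
                "qs_L_m2_d": hyd.qs,
                "mean_depth_m": hyd.mean_depth,
                "rho_per_d": hyd.rho,
                "hrt_yr": hyd.hrt_days / DAYS_PER_YEAR,
                "doc_in_mg_L": b.c_in,
                "loading_mgC_m2_d": b.loading,
                "sigma_per_d": b.sigma,
                "retention_frac": b.retention,
                "available_flux_mgC_m2_d": b.available_flux,
                "advected_flux_mgC_m2_d": b.advected_flux,
                "doc_out_mg_L": b.c_out,
                "v_doc_mm_d": b.v_doc,
            }
        )
    return pd.DataFrame(rows)


def read_fa_profiles(path) -> list[FattyAcidProfile]:
    """Read consumer fatty-acid profiles from CSV.

    Expected columns: ``treatment_id, diet_allo_fraction, <fatty acids...>,
    omega3_omega6``.  Fatty-acid columns are renormalized to sum to 1.
    """
    df = pd.read_csv(path)
    meta = {"treatment_id", "diet_allo_fraction", "omega3_omega6"}
    missing = meta - set(df.columns)
    if missing:
        raise DomainError(f"fatty-acid table missing columns: {sorted(missing)}")
    fa_cols = [c for c in df.columns if c not in meta]
    if not fa_cols:
        raise DomainError("fatty-acid table has no fatty-acid columns")
    out = []
    for _, row in df.iterrows():
        vals = row[fa_cols].to_numpy(dtype=float)
        if np.any(vals < 0) or vals.sum() <= 0:
            raise DomainError(f"invalid fatty-acid proportions for {row['treatment_id']}")
        props = dict(zip(fa_cols, vals / vals.sum()))
        out.append(
            FattyAcidProfile(
                treatment_id=str(row["treatment_id"]),
                diet_allo_fraction=float(row["diet_allo_fraction"]),
                fa_proportions=props,
                omega_ratio=float(row["omega3_omega6"]),
            )
        )
    return out


def fa_profiles_to_frame(profiles: list[FattyAcidProfile]) -> pd.DataFrame:
    names = sorted(profiles[0].fa_proportions)
    recs = []
    for p in profiles:
        rec = {"treatment_id": p.treatment_id, "diet_allo_fraction": p.diet_allo_fraction}
        rec.update({n: p.fa_proportions[n] for n in names})
        rec["omega3_omega6"] = p.omega_ratio
        recs.append(rec)
    return pd.DataFrame(recs)


def write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
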