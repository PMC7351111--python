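"""Clonogenic surviving-fraction curves with replicate aggregation.

Each replicate is normalized by its own plating efficiency (colonies per
cell plated in the untreated well) before averaging, so SF(0) = 1 exactly by
construction.  Dispersion across replicates is SEM by default, switchable to
SD to match datasets reported either way.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["surviving_fraction", "validate_survival_table"]

SURVIVAL_COLUMNS = ["condition", "dose", "replicate", "cells_plated", "colonies"]


def validate_survival_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SURVIVAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"survival table missing columns: {missing}")
    if (table["dose"] < 0).any():
        raise ValueError("doses must be >= 0")
    if (table["colonies"] < 0).any() or (table["colonies"] > table["cells_plated"]).any():
        raise ValueError("colonies must lie in [0, cells_plated]")
    for (cond, rep), grp in table.groupby(["condition", "replicate"]):
        if not (grp["dose"] == 0).any():
            raise ValueError(f"missing dose-0 row for condition {cond!r} replicate {rep!r}")
    return table


def surviving_fraction(table: pd.DataFrame, dispersion: str = "sem") -> pd.DataFrame:
    """Per-dose surviving fraction, normalized per replicate by plating efficiency.

    For each (condition, replicate): ``PE = colonies/plated`` at dose 0 and
    ``SF(d) = (colonies/plated at d) / PE``; then the mean and SEM (or SD,
    per ``dispersion``) across replicates.  Returns columns ``condition``,
    ``dose``, ``mean_sf``, ``err_sf``, ``n_replicates``.
    """
    if dispersion not in ("sem", "sd"):
        raise ValueError("dispersion must be 'sem' or 'sd'")
    validate_survival_table(table)
    per_rep = []
    for (cond, rep), grp in table.groupby(["condition", "replicate"], sort=True):
        zero = grp[grp["dose"] == 0]
        pe = float(zero["colonies"].sum() / zero["cells_plated"].sum())
        if pe <= 0:
            raise ValueError(f"no colonies in untreated control (condition {cond!r}, replicate {rep!r})")
        for _, row in grp.iterrows():
            sf = (row["colonies"] / row["cells_plated"]) / pe
            per_rep.append({"condition": cond, "dose": float(row["dose"]), "replicate": rep, "sf": sf})
    per_rep = pd.DataFrame(per_rep)
    rows = []
    for (cond, dose), grp in per_rep.groupby(["condition", "dose"], sort=True):
        sfs = grp["sf"].to_numpy(float)
        n = len(sfs)
        if n > 1:
            sd = sfs.std(ddof=1)
            err = sd / np.sqrt(n) if dispersion == "sem" else sd
        else:
            err = float("nan")
        rows.append(
            {
                "condition": cond,
                "dose": dose,
                "mean_sf": float(sfs.mean()),
                "err_sf": float(err),
                "n_replicates": n,
            }
        )
    return pd.DataFrame(rows)
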