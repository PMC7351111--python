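"""Nuclear-foci counting and the cells-above-threshold burden statistic.

Detection runs Laplacian-of-Gaussian blob detection on a max-intensity
projection of each z-stack, restricted to the supplied nucleus masks, with
the intensity threshold expressed relative to the nuclear median so counts
are invariant to global gain.  The burden statistic is the percentage of
cells with strictly more than ``threshold`` foci, summarized per experiment
and then as mean +/- SEM across experiments.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from skimage.feature import blob_log

from .rois import ImageStack

__all__ = ["detect_foci", "foci_fraction", "compare_foci", "validate_foci_table"]

FOCI_COLUMNS = ["experiment", "condition", "timepoint_h", "cell_id", "n_foci"]


def validate_foci_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FOCI_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"foci table missing columns: {missing}")
    if (table["n_foci"] < 0).any():
        raise ValueError("foci counts must be >= 0")
    keys = table[["experiment", "condition", "timepoint_h", "cell_id"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (experiment, condition, timepoint, cell) rows")
    return table


def detect_foci(
    stack: ImageStack,
    nucleus_masks: np.ndarray,
    min_sigma: float = 1.0,
    max_sigma: float = 3.0,
    rel_threshold: float = 0.35,
    experiment: str = "exp0",
    condition: str = "",
    timepoint_h: float = 0.0,
) -> pd.DataFrame:
    """Count LoG blobs per nucleus on a max-intensity projection.

    ``nucleus_masks`` is a labeled 2D image (0 = background, k = nucleus k).
    ``rel_threshold`` scales the LoG response cutoff relative to the median
    intensity inside the nuclei, which makes counts gain-invariant.
    """
    masks = np.asarray(nucleus_masks)
    if masks.max() == 0:
        raise ValueError("empty nucleus mask: no labeled nuclei")
    if not stack.has_z:
        warnings.warn("stack has no z dimension; treating as a single plane", stacklevel=2)
    proj = stack.plane(0).astype(float)
    if proj.shape != masks.shape:
        raise ValueError("mask shape does not match image shape")

    nuc_median = float(np.median(proj[masks > 0]))
    if nuc_median <= 0:
        raise ValueError("nuclear median intensity is zero; cannot set relative threshold")
    norm = proj / nuc_median
    blobs = blob_log(norm, min_sigma=min_sigma, max_sigma=max_sigma, num_sigma=5, threshold=rel_threshold)

    labels = sorted(int(k) for k in np.unique(masks) if k != 0)
    counts = dict.fromkeys(labels, 0)
    for y, x, _sigma in blobs:
        lab = int(masks[int(round(y)), int(round(x))])
        if lab > 0:
            counts[lab] += 1
    return pd.DataFrame(
        {
            "experiment": experiment,
            "condition": condition,
            "timepoint_h": float(timepoint_h),
            "cell_id": [f"nucleus{k:03d}" for k in labels],
            "n_foci": [counts[k] for k in labels],
        }
    )


def foci_fraction(table: pd.DataFrame, threshold: int = 10) -> pd.DataFrame:
    """Percentage of cells with strictly more than ``threshold`` foci.

    Computed per (condition, timepoint, experiment), then averaged across
    experiments: returns columns ``condition``, ``timepoint_h``,
    ``mean_pct``, ``sem_pct``, ``n_experiments`` plus the per-experiment
    percentages in ``per_experiment_pct``.
    """
    if int(threshold) < 0:
        raise ValueError("threshold must be a non-negative integer")
    validate_foci_table(table)
    grouped = (
        table.assign(above=table["n_foci"] > int(threshold))
        .groupby(["condition", "timepoint_h", "experiment"], sort=True)["above"]
        .agg(["sum", "count"])
        .reset_index()
    )
    # 100 * hits / total, in this exact order: bit-identical to a plain loop
    per_exp = grouped.assign(pct=100.0 * grouped["sum"] / grouped["count"])
    rows = []
    for (cond, tp), grp in per_exp.groupby(["condition", "timepoint_h"], sort=True):
        pcts = grp["pct"].to_numpy(float)
        n = len(pcts)
        rows.append(
            {
                "condition": cond,
                "timepoint_h": tp,
                "mean_pct": float(pcts.mean()),
                "sem_pct": float(pcts.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
                "n_experiments": n,
                "per_experiment_pct": tuple(float(p) for p in pcts),
            }
        )
    return pd.DataFrame(rows)


def compare_foci(summary_a: pd.DataFrame, summary_b: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Two-sample Student's t-test on per-experiment fractions at each timepoint."""
    rows = []
    b_by_tp = {row["timepoint_h"]: row for _, row in summary_b.iterrows()}
    for _, a in summary_a.iterrows():
        tp = a["timepoint_h"]
        if tp not in b_by_tp:
            raise ValueError(f"timepoint {tp} h missing from second condition")
        b = b_by_tp[tp]
        xa = np.asarray(a["per_experiment_pct"], float)
        xb = np.asarray(b["per_experiment_pct"], float)
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError("need >= 2 experiments per condition for a t-test")
        if xa.std() == 0 and xb.std() == 0 and xa.mean() == xb.mean():
            p = 1.0
        else:
            p = float(stats.ttest_ind(xa, xb, equal_var=True).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append({"timepoint_h": float(tp), "p": p, "significant": p < alpha})
    return pd.DataFrame(rows)
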