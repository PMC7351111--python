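"""Relative stripe-brightness statistic: per-cell curves, aggregation, comparison.

The per-cell statistic is the background-subtracted ratio

    Sx = (Ax - B) / (Cx - B)

where Ax is the mean stripe intensity, Cx the mean intensity of the rest of
the nucleus and B the field background.  Sx = 1 means no enrichment at the
stripe.  Because it is a ratio of background-subtracted means, Sx is
invariant under any affine intensity transform of the whole frame (gain and
offset), which also cancels photobleaching.

Aggregation follows the convention of the source assay: the cross-cell mean
with SEM = sample standard deviation / sqrt(n_cells) at each timepoint, then
an *additive* shift so the pre-irradiation mean equals exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .rois import CellMeasurement

__all__ = [
    "DegenerateContrastError",
    "RecruitmentCurve",
    "AggregateCurve",
    "compute_sx",
    "curves_from_measurements",
    "aggregate",
    "normalize_to_t0",
    "compare_conditions",
    "significance_tier",
    "fit_plateau",
]

SIGNIFICANCE_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class DegenerateContrastError(ValueError):
    """Raised when the nucleus is not brighter than the background (Cx <= B)."""


@dataclass
class RecruitmentCurve:
    """Per-cell Sx time series."""

    cell_id: str
    t: np.ndarray
    sx: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.sx = np.asarray(self.sx, dtype=float)
        if self.t.shape != self.sx.shape:
            raise ValueError("t and sx must have the same length")


@dataclass
class AggregateCurve:
    """Cross-cell mean curve with SEM and the additive normalization offset."""

    t: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_cells: int
    condition: str = ""
    pre_index: int = 0  # index of the pre-irradiation timepoint
    offset: float | None = None  # delta subtracted by normalize_to_t0; None if raw


def compute_sx(m: CellMeasurement) -> float:
    """Background-subtracted stripe/nucleus contrast (Ax - B) / (Cx - B)."""
    if m.cx <= m.b:
        raise DegenerateContrastError(
            f"degenerate contrast for cell {m.cell_id!r} frame {m.frame}: Cx={m.cx:.4g} <= B={m.b:.4g}"
        )
    return (m.ax - m.b) / (m.cx - m.b)


def curves_from_measurements(measurements: list[CellMeasurement]) -> list[RecruitmentCurve]:
    """Group measurements by cell and convert each to an Sx time series."""
    by_cell: dict[str, list[CellMeasurement]] = {}
    for m in measurements:
        by_cell.setdefault(m.cell_id, []).append(m)
    curves = []
    for cell_id in sorted(by_cell):
        ms = sorted(by_cell[cell_id], key=lambda m: m.frame)
        curves.append(
            RecruitmentCurve(
                cell_id=cell_id,
                t=np.array([m.t for m in ms]),
                sx=np.array([compute_sx(m) for m in ms]),
            )
        )
    return curves


def _sx_matrix(curves: list[RecruitmentCurve]) -> tuple[np.ndarray, np.ndarray]:
    if len(curves) < 2:
        raise ValueError("need >= 2 cells (SEM is undefined otherwise)")
    t0 = curves[0].t
    for c in curves[1:]:
        if c.t.shape != t0.shape or not np.allclose(c.t, t0):
            raise ValueError(f"cell {c.cell_id!r} is on a different timepoint grid")
    return t0, np.vstack([c.sx for c in curves])


def aggregate(curves: list[RecruitmentCurve], condition: str = "", pre_index: int = 0) -> AggregateCurve:
    """Cross-cell mean and SEM (sample sd / sqrt(n_cells)) per timepoint."""
    t, mat = _sx_matrix(curves)
    n = mat.shape[0]
    return AggregateCurve(
        t=t,
        mean=mat.mean(axis=0),
        sem=mat.std(axis=0, ddof=1) / np.sqrt(n),
        n_cells=n,
        condition=condition,
        pre_index=pre_index,
    )


def normalize_to_t0(agg: AggregateCurve) -> AggregateCurve:
    """Shift the mean curve additively so the pre-irradiation mean equals 1.

    The offset ``delta = mean(t_pre) - 1`` is subtracted from the mean at
    every timepoint (e.g. a pre-irradiation mean of 1.12 subtracts 0.12
    everywhere; 0.9 adds 0.1).  SEM values are untouched — an additive shift
    does not alter dispersion.  Idempotent.
    """
    if not (0 <= agg.pre_index < len(agg.t)):
        raise ValueError(f"pre-irradiation timepoint index {agg.pre_index} missing from curve")
    delta = float(agg.mean[agg.pre_index]) - 1.0
    mean = agg.mean - delta
    mean[agg.pre_index] = 1.0  # exact by contract, immune to float cancellation
    prior = agg.offset or 0.0
    return replace(agg, mean=mean, offset=prior + delta)


def significance_tier(p: float, thresholds=SIGNIFICANCE_TIERS) -> str:
    """Map a p-value to the conventional star tier; 'ns' above 0.05."""
    for cutoff, tier in thresholds:
        if p < cutoff:
            return tier
    return "ns"


def compare_conditions(
    curves_a: list[RecruitmentCurve],
    curves_b: list[RecruitmentCurve],
    welch: bool = False,
) -> pd.DataFrame:
    """Per-timepoint two-sample two-tailed t-test on per-cell Sx values.

    Classical equal-variance Student's t by default; ``welch=True`` switches
    to the unequal-variance variant.  No multiple-testing correction is
    applied across timepoints.  Returns columns ``t_s``, ``p``, ``tier``.
    """
    t_a, mat_a = _sx_matrix(curves_a)
    t_b, mat_b = _sx_matrix(curves_b)
    if t_a.shape != t_b.shape or not np.allclose(t_a, t_b):
        raise ValueError("conditions must share the timepoint grid")
    rows = []
    for j, t in enumerate(t_a):
        a, b = mat_a[:, j], mat_b[:, j]
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            p = 1.0  # identical degenerate groups: no evidence by convention
        else:
            p = float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append({"t_s": float(t), "p": p, "tier": significance_tier(p)})
    return pd.DataFrame(rows)


def fit_plateau(agg: AggregateCurve) -> dict[str, float]:
    """Estimate the recruitment amplitude from a normalized mean curve.

    Fits ``S(t) = 1 + A * (1 - exp(-k * t))`` by least squares (post-lag
    frames only implicitly: the pre-irradiation point anchors S = 1) and
    returns ``{"amplitude": A, "rate": k}``.
    """
    if agg.offset is None:
        agg = normalize_to_t0(agg)
    t = agg.t - agg.t[agg.pre_index]

    def model(t, a, k):
        return 1.0 + a * (1.0 - np.exp(-k * t))

    a0 = max(float(agg.mean.max()) - 1.0, 0.1)
    span = max(float(t.max()), 1.0)
    popt, _ = optimize.curve_fit(
        model, t, agg.mean, p0=(a0, 2.0 / span), bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000
    )
    return {"amplitude": float(popt[0]), "rate": float(popt[1])}


def aggregate_to_frame(agg: AggregateCurve) -> pd.DataFrame:
    """Aggregate curve as a DataFrame (t_s, mean, sem, n)."""
    return pd.DataFrame({"t_s": agg.t, "mean": agg.mean, "sem": agg.sem, "n": agg.n_cells})
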