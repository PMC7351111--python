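"""Synthetic microscopy generator: stripe movies, foci z-stacks, colony counts.

Every simulator returns its ground truth alongside the rendered data, so the
measurement and statistics stages can be validated end-to-end without any
external images.  All randomness flows from a single master seed through
:class:`numpy.random.SeedSequence` substreams, making outputs bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as ShapelyPolygon

from ._geometry import polygon_mask, translate_polygon
from .rois import CellRois, ImageStack, RoiSet

__all__ = [
    "StripeSimConfig",
    "GroundTruth",
    "FociSimResult",
    "relative_brightness",
    "simulate_stripe_movie",
    "simulate_foci_stack",
    "simulate_survival_counts",
]


# ---------------------------------------------------------------------------
# kinetic law
# ---------------------------------------------------------------------------


def relative_brightness(
    t: np.ndarray | float,
    amplitude: float,
    rate: float,
    lag: float = 0.0,
    decay: float = 0.0,
) -> np.ndarray:
    """True stripe/nucleus contrast S(t): lagged saturating rise, optional late decay.

    ``S(t) = 1`` for ``t < lag`` and
    ``S(t) = 1 + amplitude * (1 - exp(-rate*(t-lag))) * exp(-decay*(t-lag))``
    afterwards.  ``S`` is dimensionless; 1 means no enrichment at the stripe.
    """
    t = np.asarray(t, dtype=float)
    dt = np.maximum(t - lag, 0.0)
    s = 1.0 + amplitude * (1.0 - np.exp(-rate * dt)) * np.exp(-decay * dt)
    return np.where(t < lag, 1.0, s)


# ---------------------------------------------------------------------------
# stripe-movie simulation
# ---------------------------------------------------------------------------


@dataclass
class StripeSimConfig:
    """Parameters of a synthetic microirradiation movie."""

    image_shape: tuple[int, int] = (192, 256)  # (rows, cols)
    pixel_depth: float = 4095.0  # intensity ceiling
    n_cells: int = 4
    nucleus_axes: tuple[float, float] = (26.0, 18.0)  # ellipse semi-axes (x, y), px
    nucleus_jitter: float = 3.0  # per-cell center jitter, px
    stripe_width: float = 6.0  # px
    stripe_length: float = 36.0  # px
    timestamps: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0, 300.0)
    amplitude: float = 1.0  # A_true, target stripe/nucleus contrast - 1
    rate: float = 0.02  # k_true, 1/s
    lag: float = 0.0  # t_lag, s
    decay: float = 0.0  # d_true, 1/s
    i_nucleus: float = 400.0
    i_background: float = 60.0
    bleach_rate: float = 0.0  # beta, 1/s, multiplicative on the whole frame
    drift: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px/frame, all cells
    drift_random_direction: bool = False  # randomize per-cell drift direction
    shot_noise: bool = True
    read_sigma: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        ts = np.asarray(self.timestamps, float)
        if len(ts) < 2 or not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing with >= 2 frames")
        if ts[0] > self.lag:
            raise ValueError("the first (pre-irradiation) frame must precede recruitment onset")
        if not self.i_nucleus > self.i_background >= 0:
            raise ValueError("require i_nucleus > i_background >= 0")
        if self.amplitude < 0 or self.rate < 0 or self.decay < 0 or self.bleach_rate < 0:
            raise ValueError("amplitude and all rates must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.stripe_width <= 0 or self.stripe_length <= 0:
            raise ValueError("stripe dimensions must be positive")


@dataclass
class GroundTruth:
    """Everything the simulator knows: geometry, noiseless means, true contrast."""

    timestamps: np.ndarray
    s_true: np.ndarray  # shared by all cells
    rois: RoiSet  # true (drifted) polygons per cell per frame
    region_means: pd.DataFrame  # cell_id, frame, t_s, Ax, Cx, B (noiseless)


def _ellipse_polygon(center: np.ndarray, axes: tuple[float, float], n: int = 72) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + axes[0] * np.cos(theta), center[1] + axes[1] * np.sin(theta)]
    )


def _stripe_polygon(center: np.ndarray, length: float, width: float) -> np.ndarray:
    hx, hy = length / 2.0, width / 2.0
    return np.array(
        [
            [center[0] - hx, center[1] - hy],
            [center[0] + hx, center[1] - hy],
            [center[0] + hx, center[1] + hy],
            [center[0] - hx, center[1] + hy],
        ]
    )


def _place_nuclei(cfg: StripeSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered grid of nucleus centers; raises if the field cannot hold them."""
    h, w = cfg.image_shape
    ax, ay = cfg.nucleus_axes
    margin = cfg.nucleus_jitter + 4.0
    pitch_x = 2 * ax + 2 * margin
    pitch_y = 2 * ay + 2 * margin
    ncols = max(int((w - 2 * margin) // pitch_x), 1)
    nrows = max(int((h - 2 * margin) // pitch_y), 1)
    if ncols * nrows < cfg.n_cells:
        raise ValueError(
            f"field {cfg.image_shape} too small for {cfg.n_cells} nuclei of semi-axes {cfg.nucleus_axes}"
        )
    centers = []
    for i in range(cfg.n_cells):
        r, c = divmod(i, ncols)
        cx = margin + ax + c * pitch_x + pitch_x / 2 - ax
        cy = margin + ay + r * pitch_y + pitch_y / 2 - ay
        jitter = rng.uniform(-cfg.nucleus_jitter, cfg.nucleus_jitter, size=2)
        centers.append([cx + jitter[0], cy + jitter[1]])
    return np.asarray(centers)


def _remainder_polygon(nucleus: np.ndarray, stripe: np.ndarray, clearance: float = 1.5) -> np.ndarray:
    """Nucleus region avoiding the irradiated stripe: the largest piece left after
    cutting the nucleus with a full-width horizontal band around the stripe."""
    y_lo = stripe[:, 1].min() - clearance
    y_hi = stripe[:, 1].max() + clearance
    x_lo = nucleus[:, 0].min() - 10.0
    x_hi = nucleus[:, 0].max() + 10.0
    band = ShapelyPolygon([(x_lo, y_lo), (x_hi, y_lo), (x_hi, y_hi), (x_lo, y_hi)])
    diff = ShapelyPolygon(nucleus).difference(band)
    pieces = list(diff.geoms) if diff.geom_type == "MultiPolygon" else [diff]
    biggest = max(pieces, key=lambda p: p.area)
    return np.asarray(biggest.exterior.coords[:-1], dtype=float)


def simulate_stripe_movie(cfg: StripeSimConfig) -> tuple[ImageStack, RoiSet, GroundTruth]:
    """Render a microirradiation time-lapse with known recruitment kinetics.

    Each frame is ``I_bg + (I_nuc - I_bg) * M_nuc * [1 + (S(t) - 1) * M_stripe]``
    bleached by ``exp(-beta * t)``, drifted by the per-cell velocity, then
    noised (Poisson shot noise plus Gaussian read noise).  Returned ROIs track
    the drifted geometry; the :class:`GroundTruth` carries the noiseless means.
    """
    cfg.validate()
    master = np.random.SeedSequence(cfg.seed)
    ss_geom, ss_noise = master.spawn(2)
    geom_rng = np.random.default_rng(ss_geom)
    h, w = cfg.image_shape
    ts = np.asarray(cfg.timestamps, float)
    n_frames = len(ts)
    s_true = relative_brightness(ts, cfg.amplitude, cfg.rate, cfg.lag, cfg.decay)

    centers = _place_nuclei(cfg, geom_rng)
    if cfg.drift_random_direction:
        angles = geom_rng.uniform(0.0, 2.0 * math.pi, size=cfg.n_cells)
        speed = math.hypot(*cfg.drift)
        velocities = np.column_stack([speed * np.cos(angles), speed * np.sin(angles)])
    else:
        velocities = np.tile(np.asarray(cfg.drift, float), (cfg.n_cells, 1))

    nuclei, stripes, remainders = [], [], []
    for c in centers:
        nuc = _ellipse_polygon(c, cfg.nucleus_axes)
        stripe = _stripe_polygon(c, cfg.stripe_length, cfg.stripe_width)
        if not ShapelyPolygon(nuc).buffer(1e-6).contains(ShapelyPolygon(stripe)):
            raise ValueError("stripe outside nucleus")
        nuclei.append(nuc)
        stripes.append(stripe)
        remainders.append(_remainder_polygon(nuc, stripe))

    background_poly = np.array([[2.0, 2.0], [min(30.0, w - 3), 2.0], [min(30.0, w - 3), min(14.0, h - 3)], [2.0, min(14.0, h - 3)]])

    rois = RoiSet()
    frames = np.empty((n_frames, h, w), dtype=np.float64)
    records = []
    noise_rngs = [np.random.default_rng(s) for s in ss_noise.spawn(n_frames)]
    for fr in range(n_frames):
        t = ts[fr]
        img = np.full((h, w), cfg.i_background, dtype=np.float64)
        for ci in range(cfg.n_cells):
            shift = tuple(velocities[ci] * fr)
            nuc_p = translate_polygon(nuclei[ci], shift)
            stripe_p = translate_polygon(stripes[ci], shift)
            rem_p = translate_polygon(remainders[ci], shift)
            m_nuc = polygon_mask((h, w), nuc_p)
            m_stripe = polygon_mask((h, w), stripe_p)
            img[m_nuc] += cfg.i_nucleus - cfg.i_background
            img[m_stripe] += (cfg.i_nucleus - cfg.i_background) * (s_true[fr] - 1.0)
            rois.set(f"cell{ci:02d}", fr, CellRois(stripe=stripe_p, nucleus=rem_p, background=background_poly))
        img *= math.exp(-cfg.bleach_rate * t)
        # noiseless means recorded before noise
        for ci in range(cfg.n_cells):
            r = rois.get(f"cell{ci:02d}", fr)
            records.append(
                {
                    "cell_id": f"cell{ci:02d}",
                    "frame": fr,
                    "t_s": t,
                    "Ax": float(img[polygon_mask((h, w), r.stripe)].mean()),
                    "Cx": float(img[polygon_mask((h, w), r.nucleus)].mean()),
                    "B": float(img[polygon_mask((h, w), r.background)].mean()),
                }
            )
        rng = noise_rngs[fr]
        if cfg.shot_noise:
            img = rng.poisson(img).astype(np.float64)
        if cfg.read_sigma > 0:
            img = img + rng.normal(0.0, cfg.read_sigma, size=img.shape)
        frames[fr] = np.clip(img, 0.0, cfg.pixel_depth)

    stack = ImageStack(frames=frames, timestamps=ts, channel="488")
    truth = GroundTruth(timestamps=ts, s_true=s_true, rois=rois, region_means=pd.DataFrame(records))
    return stack, rois, truth


# ---------------------------------------------------------------------------
# foci z-stack simulation
# ---------------------------------------------------------------------------


@dataclass
class FociSimResult:
    """One simulated field per timepoint plus the ground truth."""

    stacks: list[ImageStack]  # one (1, Z, H, W) stack per timepoint
    nucleus_masks: list[np.ndarray]  # per timepoint: labeled 2D mask, 0 = background
    counts: pd.DataFrame  # timepoint_h, cell_id, n_foci (true counts)


def simulate_foci_stack(
    n_cells: int,
    foci_rate_per_hour: float,
    timepoints: tuple[float, ...] = (0.0, 2.0, 4.0),
    z_planes: int = 21,
    psf_sigma: tuple[float, float] = (1.3, 1.6),  # (lateral px, axial planes)
    noise: float = 4.0,  # Gaussian read-noise sigma; 0 disables
    seed: int = 0,
    nucleus_radius: float = 16.0,
    i_nucleus: float = 120.0,
    i_background: float = 20.0,
    spot_amplitude: float = 160.0,
    min_separation: float = 5.0,
) -> FociSimResult:
    """Render punctate nuclear foci whose mean count grows linearly with time.

    Per-nucleus counts are Poisson with mean ``foci_rate_per_hour * t``; each
    focus is a 3D Gaussian spot.  If a requested density cannot honor
    ``min_separation`` a warning is emitted and the spot is placed anyway
    (the returned counts stay truthful).
    """
    if z_planes < 1:
        raise ValueError("z_planes must be >= 1")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    master = np.random.SeedSequence(seed)
    streams = master.spawn(len(timepoints))

    r = nucleus_radius
    pitch = int(2 * r + 10)
    ncols = max(int(math.ceil(math.sqrt(n_cells))), 1)
    nrows = int(math.ceil(n_cells / ncols))
    h, w = nrows * pitch + 10, ncols * pitch + 10
    yy, xx = np.mgrid[0:h, 0:w]
    sig_xy, sig_z = psf_sigma

    stacks, masks_out, rows = [], [], []
    for ti, t_h in enumerate(timepoints):
        rng = np.random.default_rng(streams[ti])
        labels = np.zeros((h, w), dtype=np.int32)
        vol = np.full((z_planes, h, w), i_background, dtype=np.float64)
        for ci in range(n_cells):
            gr, gc = divmod(ci, ncols)
            cx = 5 + r + gc * pitch + (pitch / 2 - r)
            cy = 5 + r + gr * pitch + (pitch / 2 - r)
            disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
            labels[disk] = ci + 1
            vol[:, disk] = i_nucleus
            n_foci = int(rng.poisson(foci_rate_per_hour * t_h))
            placed: list[tuple[float, float]] = []
            for _ in range(n_foci):
                pos = None
                for _attempt in range(200):
                    rad = (r - 3.0) * math.sqrt(rng.uniform())
                    ang = rng.uniform(0.0, 2.0 * math.pi)
                    cand = (cx + rad * math.cos(ang), cy + rad * math.sin(ang))
                    if all(math.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_separation for p in placed):
                        pos = cand
                        break
                if pos is None:
                    warnings.warn(
                        f"could not honor min_separation={min_separation} at density "
                        f"{n_foci} foci/nucleus; placing spot anyway",
                        stacklevel=2,
                    )
                    pos = cand
                placed.append(pos)
                z0 = rng.uniform(2.0, max(z_planes - 3.0, 2.0)) if z_planes > 5 else (z_planes - 1) / 2.0
                zz = np.arange(z_planes, dtype=float)
                gz = np.exp(-0.5 * ((zz - z0) / sig_z) ** 2)
                gxy = np.exp(
                    -0.5 * (((xx - pos[0]) ** 2 + (yy - pos[1]) ** 2) / sig_xy**2)
                )
                vol += spot_amplitude * gz[:, None, None] * gxy[None, :, :]
            rows.append({"timepoint_h": float(t_h), "cell_id": f"t{ti}_cell{ci:03d}", "n_foci": n_foci})
        if noise > 0:
            vol = np.clip(vol + rng.normal(0.0, noise, size=vol.shape), 0.0, None)
        stacks.append(ImageStack(frames=vol[None, ...], timestamps=np.array([t_h * 3600.0]), channel="561"))
        masks_out.append(labels)
    return FociSimResult(stacks=stacks, nucleus_masks=masks_out, counts=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# clonogenic-survival simulation
# ---------------------------------------------------------------------------


def simulate_survival_counts(
    doses: tuple[float, ...],
    sf_model_params: dict,
    cells_plated: int = 1000,
    n_replicates: int = 3,
    seed: int = 0,
    noise: bool = True,
    condition: str = "sim",
) -> pd.DataFrame:
    """Binomial colony counts under a log-linear surviving-fraction model.

    ``sf_model_params`` holds ``plating_efficiency`` (PE in (0, 1]) and
    ``slope`` (per dose unit); the per-well success probability is
    ``p(d) = PE * exp(-slope * d)``.  With ``noise=False`` the expected count
    is returned instead of a binomial draw.
    """
    pe = float(sf_model_params["plating_efficiency"])
    slope = float(sf_model_params["slope"])
    if not 250 <= cells_plated <= 4000:
        raise ValueError("cells_plated must lie in the assay's nominal 250-4000 range")
    doses = tuple(float(d) for d in doses)
    if any(d < 0 for d in doses):
        raise ValueError("doses must be >= 0")
    if 0.0 not in doses:
        raise ValueError("a dose-0 (untreated) point is required")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for rep in range(n_replicates):
        for d in doses:
            p = pe * math.exp(-slope * d)
            if not 0.0 < p <= 1.0:
                raise ValueError(f"success probability p({d}) = {p:.4g} outside (0, 1]")
            colonies = int(rng.binomial(cells_plated, p)) if noise else int(round(cells_plated * p))
            rows.append(
                {
                    "condition": condition,
                    "dose": d,
                    "replicate": rep,
                    "cells_plated": cells_plated,
                    "colonies": colonies,
                }
            )
    return pd.DataFrame(rows)
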