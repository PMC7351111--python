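"""Image stacks, region-of-interest sets, and per-region intensity measurement.

The measurement contract is deliberately simple: every value reported
downstream is the arithmetic mean of the pixel intensities whose centers
fall inside a hand-drawn (or simulated) polygon — one stripe polygon, one
nucleus-remainder polygon and one background polygon per cell per frame.
"""

from __future__ import annotations

import json
import struct
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import signal

from ._geometry import polygon_mask, translate_polygon

__all__ = [
    "ImageStack",
    "RoiSet",
    "CellRois",
    "CellMeasurement",
    "measure_rois",
    "track_rois",
    "read_stack",
    "write_stack",
    "read_imagej_roi",
    "measurements_to_frame",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class ImageStack:
    """Time-ordered intensity frames.

    ``frames`` has shape ``(T, H, W)`` for a 2D time-lapse or
    ``(T, Z, H, W)`` when a z dimension is present (foci stacks).
    Timestamps are in seconds and must be strictly increasing.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T, H, W) or (T, Z, H, W)")
        if len(self.timestamps) != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def has_z(self) -> bool:
        return self.frames.ndim == 4

    @property
    def shape_2d(self) -> tuple[int, int]:
        return self.frames.shape[-2], self.frames.shape[-1]

    def plane(self, index: int) -> np.ndarray:
        """2D view of frame ``index``: max-intensity projection if z is present."""
        f = self.frames[index]
        return f.max(axis=0) if f.ndim == 3 else f


@dataclass
class CellRois:
    """The three polygons measured for one cell in one frame, (x, y) vertices."""

    stripe: np.ndarray
    nucleus: np.ndarray
    background: np.ndarray

    def translated(self, shift: tuple[float, float], move_background: bool = False) -> "CellRois":
        return CellRois(
            stripe=translate_polygon(self.stripe, shift),
            nucleus=translate_polygon(self.nucleus, shift),
            background=translate_polygon(self.background, shift)
            if move_background
            else np.asarray(self.background, dtype=float),
        )


class RoiSet:
    """Per-cell, per-frame polygon triplets (stripe / nucleus-remainder / background)."""

    def __init__(self) -> None:
        self._data: dict[str, dict[int, CellRois]] = {}

    def set(self, cell_id: str, frame: int, rois: CellRois) -> None:
        self._data.setdefault(str(cell_id), {})[int(frame)] = rois

    def get(self, cell_id: str, frame: int) -> CellRois:
        return self._data[str(cell_id)][int(frame)]

    @property
    def cell_ids(self) -> list[str]:
        return sorted(self._data)

    def frames(self, cell_id: str) -> list[int]:
        return sorted(self._data[str(cell_id)])

    def items(self):
        for cell_id in self.cell_ids:
            for frame in self.frames(cell_id):
                yield cell_id, frame, self._data[cell_id][frame]

    # -- JSON dialect -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "format": "recruitkin-rois-v1",
            "cells": {
                cid: {
                    str(fr): {
                        "stripe": np.asarray(r.stripe, float).tolist(),
                        "nucleus_remainder": np.asarray(r.nucleus, float).tolist(),
                        "background": np.asarray(r.background, float).tolist(),
                    }
                    for fr, r in sorted(frames.items())
                }
                for cid, frames in sorted(self._data.items())
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiSet":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != "recruitkin-rois-v1":
            raise ValueError(f"{path}: not a recruitkin ROI file")
        rs = cls()
        for cid, frames in doc["cells"].items():
            for fr, polys in frames.items():
                rs.set(
                    cid,
                    int(fr),
                    CellRois(
                        stripe=np.asarray(polys["stripe"], float),
                        nucleus=np.asarray(polys["nucleus_remainder"], float),
                        background=np.asarray(polys["background"], float),
                    ),
                )
        return rs


@dataclass
class CellMeasurement:
    """Raw region means for one cell in one frame."""

    cell_id: str
    frame: int
    t: float
    ax: float  # stripe mean
    cx: float  # nucleus-remainder mean
    b: float  # background mean

    def __post_init__(self) -> None:
        if min(self.ax, self.cx, self.b) < 0:
            raise ValueError("region means must be non-negative")


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------


def _region_mean(image: np.ndarray, polygon, what: str, cell_id: str, frame: int) -> float:
    mask = polygon_mask(image.shape, polygon)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"empty ROI: {what} polygon of cell {cell_id!r} frame {frame} rasterizes to 0 pixels")
    return float(image[mask].mean())


def measure_rois(stack: ImageStack, rois: RoiSet) -> list[CellMeasurement]:
    """Mean stripe / nucleus-remainder / background intensity per cell per frame.

    A pixel contributes iff its center falls inside the polygon (even-odd
    rule, boundary inclusive).  Frames with a z dimension are max-intensity
    projected first.
    """
    out: list[CellMeasurement] = []
    for cell_id, frame, r in rois.items():
        if not (0 <= frame < stack.n_frames):
            raise IndexError(f"frame index {frame} out of range for stack of {stack.n_frames} frames")
        img = stack.plane(frame)
        out.append(
            CellMeasurement(
                cell_id=cell_id,
                frame=frame,
                t=float(stack.timestamps[frame]),
                ax=_region_mean(img, r.stripe, "stripe", cell_id, frame),
                cx=_region_mean(img, r.nucleus, "nucleus-remainder", cell_id, frame),
                b=_region_mean(img, r.background, "background", cell_id, frame),
            )
        )
    return out


def measurements_to_frame(measurements: list[CellMeasurement]):
    """Measurements as a pandas DataFrame (columns cell_id, frame, t_s, Ax, Cx, B)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cell_id": [m.cell_id for m in measurements],
            "frame": [m.frame for m in measurements],
            "t_s": [m.t for m in measurements],
            "Ax": [m.ax for m in measurements],
            "Cx": [m.cx for m in measurements],
            "B": [m.b for m in measurements],
        }
    )


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------


def _integer_shift(ref: np.ndarray, moved: np.ndarray) -> tuple[int, int]:
    """Integer (dx, dy) such that ``moved`` best matches ``ref`` shifted by it.

    Returns (0, 0) with a warning when the correlation peak is ambiguous.
    """
    a = ref.astype(float) - ref.mean()
    b = moved.astype(float) - moved.mean()
    corr = signal.correlate(b, a, mode="full", method="auto")
    peak = corr.max()
    tol = 1e-9 * max(abs(peak), 1.0)
    ties = np.argwhere(corr >= peak - tol)
    if len(ties) != 1:
        warnings.warn("ambiguous correlation peak while tracking ROIs; assuming zero shift", stacklevel=2)
        return 0, 0
    iy, ix = ties[0]
    dy = int(iy) - (a.shape[0] - 1)
    dx = int(ix) - (a.shape[1] - 1)
    return dx, dy


def track_rois(stack: ImageStack, rois_at_t0: RoiSet, method: str = "xcorr", pad: int = 12) -> RoiSet:
    """Propagate frame-0 polygons to every frame of the stack.

    ``method="none"`` copies the t0 polygons verbatim; ``method="xcorr"``
    estimates an integer shift per frame by cross-correlating a padded
    neighborhood of each cell's nucleus between consecutive frames and
    translates the stripe and nucleus polygons accordingly (the background
    polygon describes the field of view and stays put).
    """
    if method not in ("none", "xcorr"):
        raise ValueError(f"unknown tracking method {method!r}")
    out = RoiSet()
    h, w = stack.shape_2d
    for cell_id in rois_at_t0.cell_ids:
        frames0 = rois_at_t0.frames(cell_id)
        if 0 not in frames0:
            raise ValueError(f"cell {cell_id!r} has no frame-0 ROIs to track from")
        base = rois_at_t0.get(cell_id, 0)
        if method == "none":
            for fr in range(stack.n_frames):
                out.set(cell_id, fr, base.translated((0.0, 0.0)))
            continue
        # neighborhood window around the cell at t0, fixed in the field
        verts = np.vstack([np.asarray(base.stripe, float), np.asarray(base.nucleus, float)])
        x0 = max(int(np.floor(verts[:, 0].min())) - pad, 0)
        x1 = min(int(np.ceil(verts[:, 0].max())) + pad, w - 1)
        y0 = max(int(np.floor(verts[:, 1].min())) - pad, 0)
        y1 = min(int(np.ceil(verts[:, 1].max())) + pad, h - 1)
        cum = np.zeros(2)
        out.set(cell_id, 0, base.translated((0.0, 0.0)))
        for fr in range(1, stack.n_frames):
            prev = stack.plane(fr - 1)[y0 : y1 + 1, x0 : x1 + 1]
            curr = stack.plane(fr)[y0 : y1 + 1, x0 : x1 + 1]
            dx, dy = _integer_shift(prev, curr)
            cum = cum + (dx, dy)
            out.set(cell_id, fr, base.translated(tuple(cum)))
    return out


# ---------------------------------------------------------------------------
# TIFF input/output
# ---------------------------------------------------------------------------


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as multi-page TIFF; timestamps/channel go in the description tag."""
    meta = {
        "recruitkin": {
            "timestamps_s": stack.timestamps.tolist(),
            "channel": stack.channel,
            "has_z": stack.has_z,
        }
    }
    tifffile.imwrite(str(path), stack.frames, description=json.dumps(meta))


def read_stack(path: str | Path, timestamps: np.ndarray | None = None, channel: str = "") -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack` (or any plain TIFF).

    For foreign TIFFs without embedded metadata, ``timestamps`` must be given
    (defaults to the frame index in seconds).
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    meta = None
    try:
        meta = json.loads(desc).get("recruitkin")
    except (json.JSONDecodeError, AttributeError):
        pass
    if meta is not None:
        ts = np.asarray(meta["timestamps_s"], float)
        if meta.get("has_z") and data.ndim == 3:
            data = data[None, ...]
        return ImageStack(frames=data, timestamps=ts, channel=meta.get("channel", channel))
    if data.ndim == 2:
        data = data[None, ...]
    ts = np.arange(data.shape[0], dtype=float) if timestamps is None else np.asarray(timestamps, float)
    return ImageStack(frames=data, timestamps=ts, channel=channel)


# ---------------------------------------------------------------------------
# ImageJ .roi import (optional convenience; the JSON dialect is canonical)
# ---------------------------------------------------------------------------

_IJ_POLYGON_TYPES = {0: "polygon", 3: "freehand", 4: "traced"}


def _parse_imagej_roi(buf: bytes) -> np.ndarray:
    if buf[:4] != b"Iout":
        raise ValueError("not an ImageJ ROI (missing 'Iout' magic)")
    roi_type = buf[6]
    if roi_type not in _IJ_POLYGON_TYPES:
        raise ValueError(f"unsupported ImageJ ROI type {roi_type}; only polygon-like ROIs are importable")
    top, left, _bottom, _right = struct.unpack(">4h", buf[8:16])
    (n,) = struct.unpack(">h", buf[16:18])
    xs = np.frombuffer(buf, dtype=">i2", count=n, offset=64).astype(float) + left
    ys = np.frombuffer(buf, dtype=">i2", count=n, offset=64 + 2 * n).astype(float) + top
    return np.column_stack([xs, ys])


def read_imagej_roi(path: str | Path) -> dict[str, np.ndarray]:
    """Import polygons from an ImageJ ``.roi`` file or a ``.zip`` of them.

    Returns a mapping of ROI name to an (n, 2) array of (x, y) vertices.
    """
    path = Path(path)
    if path.suffix.lower() == ".zip":
        out = {}
        with zipfile.ZipFile(path) as zf:
            for name in zf.namelist():
                out[Path(name).stem] = _parse_imagej_roi(zf.read(name))
        return out
    return {path.stem: _parse_imagej_roi(path.read_bytes())}
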