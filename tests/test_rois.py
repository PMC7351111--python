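"""Measurement module: ROI means vs brute-force oracle, tracking, file round-trips."""

import struct
import warnings

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon as ShapelyPolygon

from recruitkin import synth
from recruitkin.rois import (
    CellMeasurement,
    CellRois,
    ImageStack,
    RoiSet,
    measure_rois,
    measurements_to_frame,
    read_imagej_roi,
    read_stack,
    track_rois,
    write_stack,
)


def brute_force_mean(image, poly):
    """Independent oracle: explicit double loop, shapely point-in-polygon."""
    P = ShapelyPolygon(poly)
    vals = []
    for y in range(image.shape[0]):
        for x in range(image.shape[1]):
            if shapely.intersects(P, shapely.points([[float(x), float(y)]]))[0]:
                vals.append(image[y, x])
    return float(np.mean(vals)) if vals else None


def single_cell_roiset(stripe, nucleus, background, n_frames=1):
    rs = RoiSet()
    for fr in range(n_frames):
        rs.set("c0", fr, CellRois(stripe=np.asarray(stripe, float), nucleus=np.asarray(nucleus, float),
                                  background=np.asarray(background, float)))
    return rs


SQ1 = [(1, 1), (3, 1), (3, 3), (1, 3)]
SQ2 = [(5, 5), (7, 5), (7, 7), (5, 7)]
SQ3 = [(0, 5), (2, 5), (2, 7), (0, 7)]


class TestMeasure:
    def test_uniform_frame(self):
        stack = ImageStack(frames=np.full((1, 10, 10), 7.0), timestamps=[0.0])
        (m,) = measure_rois(stack, single_cell_roiset(SQ1, SQ2, SQ3))
        assert (m.ax, m.cx, m.b) == (7.0, 7.0, 7.0)

    def test_half_and_half_frame(self):
        img = np.empty((4, 4))
        img[:, :2] = 10.0
        img[:, 2:] = 20.0
        stack = ImageStack(frames=img[None], timestamps=[0.0])
        left_half = [(-0.5, -0.5), (1.5, -0.5), (1.5, 3.5), (-0.5, 3.5)]
        right_half = [(1.5, -0.5), (3.5, -0.5), (3.5, 3.5), (1.5, 3.5)]
        # note: x = 1.5 boundary splits between pixel centers 1 and 2
        rs = single_cell_roiset(left_half, right_half, right_half)
        (m,) = measure_rois(stack, rs)
        assert m.ax == brute_force_mean(img, left_half) == 10.0

    def test_matches_ground_truth_means(self, noiseless_movie):
        _, stack, rois, truth = noiseless_movie
        df = measurements_to_frame(measure_rois(stack, rois))
        merged = df.merge(truth.region_means, on=["cell_id", "frame"], suffixes=("", "_true"))
        for col in ("Ax", "Cx", "B"):
            assert np.allclose(merged[col], merged[f"{col}_true"])

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(8, 64, size=2)
        img = rng.uniform(0, 100, size=(h, w))
        center = rng.uniform(3, [w - 3, h - 3])
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=rng.integers(3, 8)))
        radii = rng.uniform(1.5, 6, size=len(angles))
        poly = np.column_stack([center[0] + radii * np.cos(angles), center[1] + radii * np.sin(angles)])
        expected = brute_force_mean(img, poly)
        if expected is None:
            return
        stack = ImageStack(frames=img[None], timestamps=[0.0])
        (m,) = measure_rois(stack, single_cell_roiset(poly, poly, poly))
        assert m.ax == expected  # exact, same pixels

    def test_translation_equivariance(self, rng):
        img = rng.uniform(0, 50, size=(40, 40))
        big = np.zeros((60, 60))
        big[:40, :40] = img
        shifted = np.zeros((60, 60))
        shifted[10:50, 5:45] = img
        poly = np.array([(8.2, 6.1), (18.9, 7.3), (15.5, 17.8), (7.0, 14.2)])
        s1 = ImageStack(frames=big[None], timestamps=[0.0])
        s2 = ImageStack(frames=shifted[None], timestamps=[0.0])
        (m1,) = measure_rois(s1, single_cell_roiset(poly, poly, poly))
        (m2,) = measure_rois(s2, single_cell_roiset(poly + (5, 10), poly + (5, 10), poly + (5, 10)))
        assert m1.ax == m2.ax

    def test_empty_roi_errors(self):
        stack = ImageStack(frames=np.zeros((1, 10, 10)), timestamps=[0.0])
        sliver = [(0.1, 0.1), (0.2, 0.1), (0.2, 0.2)]  # contains no pixel center
        with pytest.raises(ValueError, match="empty ROI"):
            measure_rois(stack, single_cell_roiset(sliver, SQ2, SQ3))

    def test_frame_out_of_range_errors(self):
        stack = ImageStack(frames=np.zeros((1, 10, 10)), timestamps=[0.0])
        rs = single_cell_roiset(SQ1, SQ2, SQ3, n_frames=3)
        with pytest.raises(IndexError):
            measure_rois(stack, rs)

    def test_negative_measurement_rejected(self):
        with pytest.raises(ValueError):
            CellMeasurement(cell_id="c", frame=0, t=0.0, ax=-1.0, cx=1.0, b=0.0)


class TestTrack:
    def test_method_none_identity(self, noiseless_movie):
        _, stack, rois, _ = noiseless_movie
        rs0 = RoiSet()
        for cid in rois.cell_ids:
            rs0.set(cid, 0, rois.get(cid, 0))
        tracked = track_rois(stack, rs0, method="none")
        for cid in rois.cell_ids:
            for fr in range(stack.n_frames):
                assert np.array_equal(tracked.get(cid, fr).stripe, rs0.get(cid, 0).stripe)

    def test_zero_drift_zero_shifts(self, noiseless_movie):
        _, stack, rois, _ = noiseless_movie
        rs0 = RoiSet()
        for cid in rois.cell_ids:
            rs0.set(cid, 0, rois.get(cid, 0))
        tracked = track_rois(stack, rs0, method="xcorr")
        for cid in rois.cell_ids:
            assert np.array_equal(tracked.get(cid, stack.n_frames - 1).stripe, rs0.get(cid, 0).stripe)

    def test_recovers_integer_drift(self):
        ts = tuple(np.arange(11) * 30.0)
        cfg = synth.StripeSimConfig(
            n_cells=1, image_shape=(140, 260), timestamps=ts, drift=(1.0, 0.0),
            shot_noise=False, read_sigma=0.0, seed=2,
        )
        stack, rois, _ = synth.simulate_stripe_movie(cfg)
        rs0 = RoiSet()
        rs0.set("cell00", 0, rois.get("cell00", 0))
        tracked = track_rois(stack, rs0, method="xcorr", pad=20)
        shift = tracked.get("cell00", 10).stripe - rois.get("cell00", 0).stripe
        assert np.allclose(shift, [10.0, 0.0])

    def test_ambiguous_peak_warns_and_zero_shift(self):
        stack = ImageStack(frames=np.zeros((3, 30, 30)), timestamps=[0.0, 1.0, 2.0])
        rs0 = single_cell_roiset(SQ1, SQ2, SQ3)
        with pytest.warns(UserWarning, match="ambiguous"):
            tracked = track_rois(stack, rs0, method="xcorr")
        assert np.array_equal(tracked.get("c0", 2).stripe, np.asarray(SQ1, float))

    def test_unknown_method_rejected(self, noiseless_movie):
        _, stack, rois, _ = noiseless_movie
        with pytest.raises(ValueError, match="unknown tracking method"):
            track_rois(stack, rois, method="optical-flow")


class TestIO:
    def test_tiff_roundtrip(self, tmp_path, noiseless_movie):
        _, stack, _, _ = noiseless_movie
        p = tmp_path / "stack.tif"
        write_stack(p, stack)
        back = read_stack(p)
        assert np.array_equal(back.frames, stack.frames)
        assert np.array_equal(back.timestamps, stack.timestamps)
        assert back.channel == stack.channel

    def test_roi_json_roundtrip(self, tmp_path, noiseless_movie):
        _, _, rois, _ = noiseless_movie
        p = tmp_path / "rois.json"
        rois.to_json(p)
        back = RoiSet.from_json(p)
        assert back.cell_ids == rois.cell_ids
        for cid, fr, r in rois.items():
            assert np.allclose(back.get(cid, fr).stripe, r.stripe)
            assert np.allclose(back.get(cid, fr).nucleus, r.nucleus)

    def test_imagej_roi_import(self, tmp_path):
        # minimal ImageJ polygon ROI: header + relative shorts
        xs, ys = [2, 10, 6], [3, 4, 12]
        left, top = min(xs), min(ys)
        buf = bytearray(64)
        buf[0:4] = b"Iout"
        buf[6] = 0  # polygon
        struct.pack_into(">4h", buf, 8, top, left, max(ys), max(xs))
        struct.pack_into(">h", buf, 16, len(xs))
        for x in xs:
            buf += struct.pack(">h", x - left)
        for y in ys:
            buf += struct.pack(">h", y - top)
        p = tmp_path / "cell.roi"
        p.write_bytes(bytes(buf))
        polys = read_imagej_roi(p)
        assert np.array_equal(polys["cell"], np.column_stack([xs, ys]).astype(float))


class TestImageStackInvariants:
    def test_timestamps_must_increase(self):
        with pytest.raises(ValueError):
            ImageStack(frames=np.zeros((2, 4, 4)), timestamps=[1.0, 1.0])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            ImageStack(frames=np.full((1, 4, 4), -1.0), timestamps=[0.0])

    def test_max_projection_for_z(self):
        vol = np.zeros((1, 3, 4, 4))
        vol[0, 1, 2, 2] = 9.0
        stack = ImageStack(frames=vol, timestamps=[0.0])
        assert stack.plane(0)[2, 2] == 9.0
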