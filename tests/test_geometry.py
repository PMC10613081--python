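"""Endocardial boundary extraction, landmarks and segment partitioning."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from skimage.draw import disk

from echomotion.geometry import (
    BoundaryTrace,
    ClipRejectedError,
    DegenerateBoundaryError,
    extract_endocardial_boundary,
    locate_landmarks,
    partition_segments,
    resample_sequence,
)
from echomotion.simulate import MaskSequence, PhantomSpec, simulate_clip


def _shifted(frames: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(frames)
    out[:, dy:, dx:] = frames[:, : frames.shape[1] - dy, : frames.shape[2] - dx]
    return out


class TestBoundaryExtraction:
    def test_recovers_analytic_inner_arc(self, uniform_clip):
        """Every trace point lies within 1.5 px of the simulator's exact
        endocardial coordinates, at rest and through the contraction."""
        for f in range(0, uniform_clip.masks.n_frames, 3):
            trace = extract_endocardial_boundary(uniform_clip.masks.frames[f])
            d, _ = cKDTree(uniform_clip.endo_points(f)).query(trace.points)
            assert d.max() < 1.5

    def test_recovers_arc_with_uneven_amplitudes(self):
        rng = np.random.default_rng(3)
        spec = PhantomSpec(base_amplitudes=tuple(rng.uniform(4, 6, 6)), noise=0.3, seed=3)
        clip = simulate_clip(spec, clip_id="c")
        for f in (0, 8, 12, 20):
            trace = extract_endocardial_boundary(clip.masks.frames[f])
            d, _ = cKDTree(clip.endo_points(f)).query(trace.points)
            assert d.max() < 1.5

    def test_trace_is_arc_contiguous(self, uniform_clip):
        trace = extract_endocardial_boundary(uniform_clip.masks.frames[0])
        steps = np.linalg.norm(np.diff(trace.points, axis=0), axis=1)
        assert steps.max() < np.sqrt(2)

    def test_closed_annulus_degenerate(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        rr, cc = disk((32, 32), 25)
        mask[rr, cc] = 1
        rr, cc = disk((32, 32), 17)
        mask[rr, cc] = 0
        with pytest.raises(DegenerateBoundaryError):
            extract_endocardial_boundary(mask)

    def test_solid_blob_degenerate(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        rr, cc = disk((32, 32), 20)
        mask[rr, cc] = 1
        with pytest.raises(DegenerateBoundaryError):
            extract_endocardial_boundary(mask)

    def test_speck_component_ignored(self, uniform_clip):
        mask = uniform_clip.masks.frames[0].copy()
        mask[2:4, 2:4] = 1  # tiny disconnected speck
        a = extract_endocardial_boundary(uniform_clip.masks.frames[0])
        b = extract_endocardial_boundary(mask)
        assert np.allclose(a.points, b.points)

    def test_translation_equivariance(self, uniform_clip):
        """Translating the mask translates the trace, within 1 px."""
        frame = uniform_clip.masks.frames[0]
        dy, dx = 7, 4
        shifted = _shifted(frame[None], dy, dx)[0]
        a = extract_endocardial_boundary(frame)
        b = extract_endocardial_boundary(shifted)
        moved = a.points + np.array([dx, dy])
        d, _ = cKDTree(moved).query(b.points)
        assert d.max() <= 1.0


class TestLandmarks:
    def test_apex_near_arc_midpoint_for_symmetric_phantom(self, uniform_clip):
        trace = extract_endocardial_boundary(uniform_clip.masks.frames[0])
        lm = locate_landmarks(trace)
        s = trace.arc_length
        assert abs(s[lm.apex] - s[-1] / 2) < 0.02 * s[-1]
        assert lm.left_corner == 0
        assert lm.right_corner == len(trace.points) - 1

    def test_straight_line_trace_flagged(self):
        pts = np.column_stack((np.linspace(0, 10, 50), np.zeros(50)))
        lm = locate_landmarks(BoundaryTrace(points=pts, apex=0))
        assert lm.degenerate
        assert lm.apex_distance == 0.0


class TestPartition:
    def test_equal_span_arithmetic_on_polyline(self):
        """A V-shaped polyline of total length 700 splits at arc positions
        0, 100, ..., 700; with N=2 segment 1 samples sit at arc 0 and 100."""
        # two straight legs of length 350 each
        t = np.linspace(0, 1, 3501)
        leg = 350.0
        x = np.where(t <= 0.5, t * 2 * leg * 0.6, leg * 0.6 + (t - 0.5) * 2 * leg * 0.6)
        y = np.where(t <= 0.5, -t * 2 * leg * 0.8, -leg * 0.8 + (t - 0.5) * 2 * leg * 0.8)
        trace = BoundaryTrace(points=np.column_stack((x, y)), apex=0)
        part = partition_segments(trace, n_samples=2)
        s = trace.arc_length
        assert np.allclose(s[-1], 700.0, atol=1e-6)
        # segment 1 spans arc [0, 100]: first sample at the corner, second
        # 100 arc units along the first leg
        np.testing.assert_allclose(part.points[0, 0], [0.0, 0.0], atol=1e-9)
        np.testing.assert_allclose(part.points[0, 1], [60.0, -80.0], atol=1e-6)
        np.testing.assert_allclose(part.span_bounds, np.arange(8) * 100.0, atol=1e-9)

    def test_always_6n_samples(self, uniform_clip):
        for n in (2, 5, 8):
            trace = extract_endocardial_boundary(uniform_clip.masks.frames[0])
            part = partition_segments(trace, n_samples=n)
            assert part.points.shape == (6, n, 2)

    def test_equal_spacing_within_segments(self, uniform_clip):
        trace = extract_endocardial_boundary(uniform_clip.masks.frames[0])
        part = partition_segments(trace, n_samples=8)
        for seg in part.points:
            gaps = np.linalg.norm(np.diff(seg, axis=0), axis=1)
            assert gaps.max() - gaps.min() < 0.5

    def test_lesion_sector_alignment(self, lesioned_clip):
        """The partition's segment 2 overlaps the simulator's lesioned
        angular sector by at least 80% of its arc."""
        trace = extract_endocardial_boundary(lesioned_clip.masks.frames[0])
        part = partition_segments(trace, n_samples=12)
        cx, cy = lesioned_clip.center
        phi = lesioned_clip.phi
        # simulator's segment-2 angular sector
        lo, hi = phi[0] + (phi[-1] - phi[0]) / 7, phi[0] + 2 * (phi[-1] - phi[0]) / 7
        pts = part.points[1]
        ang = np.mod(np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx) - phi[0], 2 * np.pi) + phi[0]
        inside = (ang >= lo) & (ang <= hi)
        assert inside.mean() >= 0.8

    def test_too_few_samples_rejected(self, uniform_clip):
        trace = extract_endocardial_boundary(uniform_clip.masks.frames[0])
        with pytest.raises(ValueError):
            partition_segments(trace, n_samples=1)
        short = BoundaryTrace(points=trace.points[:30], apex=15)
        with pytest.raises(DegenerateBoundaryError):
            partition_segments(short, n_samples=8)


class TestResampleSequence:
    def test_static_sequence_identical_partitions(self, static_clip):
        parts = resample_sequence(static_clip.masks, n_samples=6)
        assert len(parts) == static_clip.masks.n_frames
        for p in parts[1:]:
            np.testing.assert_allclose(p.points, parts[0].points, atol=1e-9)

    def test_translated_frame_tracks_shift(self, uniform_clip):
        frame = uniform_clip.masks.frames[0]
        dy, dx = 5, 3
        frames = np.stack([frame, _shifted(frame[None], dy, dx)[0]])
        seq = MaskSequence(frames, "t", "gt")
        parts = resample_sequence(seq, n_samples=8)
        delta = parts[1].points - parts[0].points
        np.testing.assert_allclose(delta[..., 0], dx, atol=1.0)
        np.testing.assert_allclose(delta[..., 1], dy, atol=1.0)

    def test_mostly_degenerate_clip_rejected(self):
        solid = np.zeros((48, 48), dtype=np.uint8)
        rr, cc = disk((24, 24), 15)
        solid[rr, cc] = 1
        good = simulate_clip(
            PhantomSpec(n_frames=4, image_size=(48, 48), endo_radius=14, wall_thickness=5,
                        base_amplitudes=(2.0,) * 6),
            clip_id="g",
        ).masks.frames
        frames = np.concatenate([good[:1], np.stack([solid] * 3)])
        seq = MaskSequence(frames, "bad", "gt")
        with pytest.raises(ClipRejectedError):
            resample_sequence(seq)

    def test_degenerate_fail_mode_raises(self):
        solid = np.zeros((48, 48), dtype=np.uint8)
        rr, cc = disk((24, 24), 15)
        solid[rr, cc] = 1
        seq = MaskSequence(np.stack([solid] * 2), "bad", "gt")
        with pytest.raises(DegenerateBoundaryError):
            resample_sequence(seq, on_degenerate="fail")
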