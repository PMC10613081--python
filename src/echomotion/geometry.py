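"""Endocardial boundary extraction and segment partitioning.

The LV wall in an A4C mask is a horseshoe whose concave side faces the
blood pool.  The endocardial (inner) boundary is recovered by casting rays
from the centroid of the enclosed cavity and keeping the first wall
crossing along each ray; rays that never hit the wall mark the basal
opening, so the boundary comes out as an open arc running from the left
basal corner over the apex to the right basal corner.  The arc is then cut
into seven equal-arc-length segments; the apical cap (fourth span) is
dropped and each remaining segment is sampled with N equally spaced points,
giving index correspondence across frames of a clip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.measure import label as cc_label
from skimage.morphology import convex_hull_image

from .simulate import MaskSequence

ANALYSED_SEGMENTS = (1, 2, 3, 5, 6, 7)


class DegenerateBoundaryError(ValueError):
    """No usable endocardial arc: missing cavity, opening, or wall."""


class ClipRejectedError(ValueError):
    """Too many degenerate frames to analyse the clip."""


@dataclass
class BoundaryTrace:
    """Ordered endocardial arc for one frame.

    ``points`` runs from the left basal corner (index 0) over the apex to
    the right basal corner (last index); coordinates are (x, y) =
    (column, row) at sub-pixel resolution.
    """

    points: np.ndarray  # (n, 2) float
    apex: int
    frame_index: int = 0

    @property
    def left_corner(self) -> int:
        return 0

    @property
    def right_corner(self) -> int:
        return len(self.points) - 1

    @property
    def arc_length(self) -> np.ndarray:
        """Cumulative arc length at each trace point (starts at 0)."""
        step = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate(([0.0], np.cumsum(step)))


@dataclass
class SegmentPartition:
    """N sampled endocardial points for each analysed segment of one frame."""

    points: np.ndarray        # (6, N, 2) float (x, y)
    segment_ids: tuple[int, ...]
    span_bounds: np.ndarray   # (8,) arc-length positions of the 7 span edges
    frame_index: int = 0

    @property
    def n_samples(self) -> int:
        return self.points.shape[1]


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Binary mask restricted to its largest connected component."""
    lab, n = cc_label(mask > 0, connectivity=2, return_num=True)
    if n <= 1:
        return (mask > 0).astype(np.uint8)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return (lab == sizes.argmax()).astype(np.uint8)


def cavity_centroid(mask: np.ndarray, min_area: int = 9) -> tuple[float, float]:
    """Centroid (x, y) of the cavity enclosed by the wall's concave side.

    The cavity is the largest background component inside the convex hull
    of the wall.  Raises :class:`DegenerateBoundaryError` when no cavity of
    at least ``min_area`` pixels exists (solid blob or empty mask).
    """
    fg = mask > 0
    if not fg.any():
        raise DegenerateBoundaryError("empty mask")
    hull = convex_hull_image(fg)
    cavity = hull & ~fg
    lab, n = cc_label(cavity, connectivity=1, return_num=True)
    if n == 0:
        raise DegenerateBoundaryError("no cavity: mask is a solid blob")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    if sizes.max() < min_area:
        raise DegenerateBoundaryError("cavity too small to anchor rays")
    ys, xs = np.nonzero(lab == sizes.argmax())
    return float(xs.mean()), float(ys.mean())


def _ray_origin(fg: np.ndarray) -> tuple[float, float]:
    """A point inside the cavity to anchor ray casting.

    The wall-pixel centroid of a horseshoe lies inside the enclosed cavity
    and is cheap to compute; when it does not (oddly shaped or broken
    masks) fall back to the hull-based cavity centroid.
    """
    ys, xs = np.nonzero(fg)
    if ys.size == 0:
        raise DegenerateBoundaryError("empty mask")
    cx, cy = float(xs.mean()), float(ys.mean())
    if fg[int(round(cy)), int(round(cx))]:
        return cavity_centroid(fg)
    return cx, cy


@lru_cache(maxsize=8)
def _unit_rays(n_rays: int):
    theta = np.linspace(0.0, 2 * np.pi, n_rays, endpoint=False)
    return theta, np.cos(theta), np.sin(theta)


def _first_hits(
    fg: np.ndarray,
    center: tuple[float, float],
    n_rays: int,
    radial_step: float,
):
    """First wall crossing along each of ``n_rays`` rays from ``center``.

    Returns (theta, r_first, hits_any); r_first is refined half a step
    inward and is NaN for rays that never cross the wall.  Rays sample a
    zero-padded copy of the mask, so a wall touching the image border is
    read as background just outside it.
    """
    cx, cy = center
    h, w = fg.shape
    ys_fg, xs_fg = np.nonzero(fg)
    d2 = (xs_fg - cx) ** 2 + (ys_fg - cy) ** 2
    # rays only need to span the radial band that holds foreground pixels
    r_hi = float(np.sqrt(d2.max())) + 1.0
    r_lo = max(float(np.sqrt(d2.min())) - 1.0, radial_step)
    radii = np.arange(r_lo, r_hi, radial_step)
    theta, cos_t, sin_t = _unit_rays(n_rays)
    xi = np.multiply.outer(cos_t, radii)
    xi += cx + 1.5  # +0.5 rounds to nearest pixel, +1 shifts into the pad
    yi = np.multiply.outer(sin_t, radii)
    yi += cy + 1.5
    xi = xi.astype(np.int32)
    yi = yi.astype(np.int32)
    np.clip(xi, 0, w + 1, out=xi)
    np.clip(yi, 0, h + 1, out=yi)
    padded = np.zeros((h + 2, w + 2), dtype=np.uint8)
    padded[1 : h + 1, 1 : w + 1] = fg
    hit = padded[yi, xi]
    hits_any = hit.any(axis=1)
    r_first = np.where(hits_any, radii[hit.argmax(axis=1)] - radial_step / 2.0, np.nan)
    return theta, r_first, hits_any


def _fit_circle_center(pts: np.ndarray) -> tuple[float, float]:
    """Least-squares (Kasa) circle fit; returns the fitted center (x, y)."""
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack((2 * x, 2 * y, np.ones(len(pts))))
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(sol[0]), float(sol[1])


def _longest_run(hits_any: np.ndarray) -> np.ndarray:
    """Indices of the longest circularly-contiguous run of hitting rays."""
    n = hits_any.size
    gap = np.flatnonzero(~hits_any)
    order = np.roll(np.arange(n), -int(gap[0]))
    idx = np.flatnonzero(hits_any[order])
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    runs = [idx[s : e + 1] for s, e in zip(starts, ends)]
    return order[max(runs, key=len)]


def _trim_cap_faces(
    r: np.ndarray, max_trim: int = 40, jump: float = 1.0, lookahead: int = 3
) -> tuple[int, int]:
    """Indices (lo, hi) after dropping steep radial end points.

    Near the basal corners a ray can graze the radial end-cap face of the
    wall instead of the endocardial arc; such points sit well outside the
    arc radius a few samples inward and are stripped from both ends.
    """
    lo, hi = 0, r.size
    for _ in range(max_trim):
        if hi - lo < 2 * lookahead + 2:
            break
        if r[lo] - r[lo + lookahead] > jump:
            lo += 1
        elif r[hi - 1] - r[hi - 1 - lookahead] > jump:
            hi -= 1
        else:
            break
    # shallow grazing of a cap face shows as a monotone radius ramp toward
    # the end; strip it too (capped so real arc points are barely touched)
    for _ in range(12):
        if hi - lo < 2 * lookahead + 2:
            break
        if r[lo] - r[lo + 1] > 0.05:
            lo += 1
        else:
            break
    for _ in range(12):
        if hi - lo < 2 * lookahead + 2:
            break
        if r[hi - 1] - r[hi - 2] > 0.05:
            hi -= 1
        else:
            break
    return lo, hi


def extract_endocardial_boundary(
    mask: np.ndarray,
    frame_index: int = 0,
    n_rays: int = 540,
    radial_step: float = 0.25,
) -> BoundaryTrace:
    """Trace the inner wall edge of one frame as an ordered open arc.

    Works on the largest connected component.  Rays cast from inside the
    cavity record their first wall crossing; the longest contiguous run of
    hitting rays forms the arc.  Two passes are used: the cavity centroid
    anchors a provisional trace, and a least-squares circle fit of that
    trace re-centers the rays so that corner points are sampled cleanly.
    A mask whose wall surrounds the cavity completely (no basal opening)
    is degenerate.
    """
    fg = largest_component(mask)
    center = _ray_origin(fg)
    for _pass in range(2):
        # the provisional pass only anchors the circle fit; keep it coarse
        pass_rays = max(n_rays // 3, 90) if _pass == 0 else n_rays
        pass_step = max(radial_step * 2, 0.5) if _pass == 0 else radial_step
        theta, r_first, hits_any = _first_hits(fg, center, pass_rays, pass_step)
        if not hits_any.any():
            raise DegenerateBoundaryError("no wall visible from the ray origin")
        if hits_any.all():
            raise DegenerateBoundaryError("no basal opening: boundary is closed")
        rays = _longest_run(hits_any)
        cx, cy = center
        pts = np.column_stack(
            (
                cx + r_first[rays] * np.cos(theta[rays]),
                cy + r_first[rays] * np.sin(theta[rays]),
            )
        )
        if _pass == 0:
            center = _fit_circle_center(pts)

    lo, hi = _trim_cap_faces(r_first[rays])
    rays = rays[lo:hi]
    # light radial smoothing removes sub-pixel stair-steps that would
    # otherwise inflate the local arc length non-uniformly
    r_run = gaussian_filter1d(r_first[rays], 2.0, mode="nearest")
    pts = np.column_stack(
        (cx + r_run * np.cos(theta[rays]), cy + r_run * np.sin(theta[rays]))
    )
    if pts[0, 0] > pts[-1, 0]:  # orient left corner first
        pts = pts[::-1]
    trace = BoundaryTrace(points=pts, apex=0, frame_index=frame_index)
    trace.apex = locate_landmarks(trace).apex
    return trace


@dataclass
class Landmarks:
    """Corner and apex indices of a boundary trace."""

    left_corner: int
    apex: int
    right_corner: int
    apex_distance: float
    degenerate: bool = False


def locate_landmarks(trace: BoundaryTrace) -> Landmarks:
    """Locate the basal corners and the apex.

    Corners are the arc endpoints; the apex is the trace point farthest
    (perpendicular distance) from the corner-to-corner chord, ties broken
    toward the smaller index.  A straight-line trace has apex distance 0
    and is flagged degenerate.
    """
    pts = trace.points
    if len(pts) < 3:
        raise DegenerateBoundaryError("trace too short for landmarks")
    a, b = pts[0], pts[-1]
    chord = b - a
    norm = np.linalg.norm(chord)
    if norm == 0:
        raise DegenerateBoundaryError("coincident corners")
    rel = pts - a
    d = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / norm
    apex = int(d.argmax())
    dist = float(d[apex])
    return Landmarks(0, apex, len(pts) - 1, dist, degenerate=dist < 1e-9)


def partition_segments(
    trace: BoundaryTrace,
    landmarks: Landmarks | None = None,
    n_samples: int = 8,
) -> SegmentPartition:
    """Split the arc into 7 equal-arc spans, drop the apical cap, sample N.

    Spans are numbered 1..7 from the left corner; span 4 (the apical cap)
    carries no samples because it shows no inward motion in the A4C view.
    Each retained span is sampled with ``n_samples`` points at equal arc
    spacing, endpoints included.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if landmarks is None:
        landmarks = locate_landmarks(trace)
    if landmarks.degenerate:
        raise DegenerateBoundaryError("degenerate (straight-line) trace")
    if len(trace.points) < 7 * n_samples:
        raise DegenerateBoundaryError(
            f"trace has {len(trace.points)} points; need >= {7 * n_samples}"
        )
    s = trace.arc_length
    total = s[-1]
    bounds = np.linspace(0.0, total, 8)
    spans = [0, 1, 2, 4, 5, 6]  # span 3 (0-based) is the apical cap
    out = np.empty((6, n_samples, 2))
    for row, k in enumerate(spans):
        pos = np.linspace(bounds[k], bounds[k + 1], n_samples)
        out[row, :, 0] = np.interp(pos, s, trace.points[:, 0])
        out[row, :, 1] = np.interp(pos, s, trace.points[:, 1])
    return SegmentPartition(
        points=out,
        segment_ids=ANALYSED_SEGMENTS,
        span_bounds=bounds,
        frame_index=trace.frame_index,
    )


def resample_sequence(
    seq: MaskSequence,
    n_samples: int = 8,
    on_degenerate: str = "skip",
    max_degenerate_frac: float = 0.5,
) -> list[SegmentPartition]:
    """Per-frame segment partitions with index correspondence across frames.

    Sample n of segment s sits at the same arc fraction (anchored at the
    left corner) in every frame, which is what lets displacements be read
    off by direct index subtraction.  Degenerate frames are skipped with a
    warning (``on_degenerate='skip'``) or raise (``'fail'``); a clip with
    more than ``max_degenerate_frac`` degenerate frames is rejected.
    """
    if on_degenerate not in ("skip", "fail"):
        raise ValueError("on_degenerate must be 'skip' or 'fail'")
    partitions: list[SegmentPartition] = []
    n_bad = 0
    for k in range(seq.n_frames):
        try:
            trace = extract_endocardial_boundary(seq.frames[k], frame_index=k)
            partitions.append(partition_segments(trace, n_samples=n_samples))
        except DegenerateBoundaryError as exc:
            if on_degenerate == "fail":
                raise
            n_bad += 1
            warnings.warn(f"{seq.clip_id}/{seq.source} frame {k} degenerate: {exc}")
    if n_bad > max_degenerate_frac * seq.n_frames:
        raise ClipRejectedError(
            f"{seq.clip_id}/{seq.source}: {n_bad}/{seq.n_frames} frames degenerate"
        )
    return partitions


def render_overlay(mask: np.ndarray, trace: BoundaryTrace, partition: SegmentPartition, path) -> None:
    """Write a debug rendering of the trace, landmarks and segment samples."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(mask, cmap="gray", interpolation="nearest")
    ax.plot(trace.points[:, 0], trace.points[:, 1], "-", lw=1, color="cyan")
    for row, seg in enumerate(partition.segment_ids):
        p = partition.points[row]
        ax.plot(p[:, 0], p[:, 1], ".", ms=4, label=f"seg {seg}")
    apex = trace.points[trace.apex]
    ax.plot(*apex, "r*", ms=10)
    ax.legend(fontsize=6, loc="lower right")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
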