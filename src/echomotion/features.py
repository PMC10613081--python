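"""Per-segment displacement curves and the 6-dimensional motion feature.

For each analysed wall segment the displacement at frame t is the mean L1
distance between its N sampled endocardial points in frame t and in the
reference frame t_r (the first frame by default):

    d[s, t] = (1/N) * sum_n |x_n(t_r) - x_n(t)| + |y_n(t_r) - y_n(t)|

The motion feature MF is the per-segment maximum of d over the cycle,
normalized to unity by the largest of the six maxima, so MF lies in
[0, 1]^6 and hypokinetic (infarcted) segments show up as small entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SegmentPartition

ANALYSED_SEGMENTS = (1, 2, 3, 5, 6, 7)


@dataclass
class DisplacementCurves:
    """Displacement matrix over segments x non-reference frames."""

    d: np.ndarray               # (6, T-1), pixel units, >= 0
    frame_indices: np.ndarray   # (T-1,) original frame index of each column
    reference_frame: int


@dataclass
class MotionFeature:
    """Normalized per-segment maximum displacement for one clip/source."""

    mf: np.ndarray              # (6,) values in [0, 1]
    norm_constant: float        # largest per-segment maximum, pixels
    zero_motion: bool = False   # guard: no segment moved at all


def displacement(ref: SegmentPartition, cur: SegmentPartition) -> np.ndarray:
    """Mean per-point L1 displacement of each segment between two frames."""
    if ref.points.shape != cur.points.shape:
        raise ValueError("partitions must have identical shape (same N)")
    if ref.segment_ids != cur.segment_ids:
        raise ValueError("partitions must share segment ordering")
    return np.abs(ref.points - cur.points).sum(axis=2).mean(axis=1)


def displacement_curves(
    partitions: list[SegmentPartition],
    reference_frame: int | None = None,
) -> DisplacementCurves:
    """Displacement of every segment at every non-reference frame.

    ``partitions`` is the per-frame output of the geometry stage (frames
    dropped as degenerate are simply absent).  The reference is the first
    frame of the sequence — the earliest available partition — unless
    ``reference_frame`` picks another one (e.g. a known end-diastole).
    """
    if len(partitions) < 2:
        raise ValueError("need at least two frames to compute displacement")
    if reference_frame is None:
        reference_frame = min(p.frame_index for p in partitions)
    by_frame = {p.frame_index: p for p in partitions}
    if reference_frame not in by_frame:
        raise ValueError(f"reference frame {reference_frame} missing from partitions")
    ref = by_frame[reference_frame]
    others = [p for p in partitions if p.frame_index != reference_frame]
    d = np.column_stack([displacement(ref, p) for p in others])
    idx = np.array([p.frame_index for p in others])
    return DisplacementCurves(d=d, frame_indices=idx, reference_frame=reference_frame)


def motion_feature(curves: DisplacementCurves) -> MotionFeature:
    """Per-segment maximum displacement over time, normalized to unity.

    If no segment moved (all-zero curves) the guard fires and an all-zero
    feature is returned with ``zero_motion=True``.
    """
    peaks = curves.d.max(axis=1)
    top = float(peaks.max())
    if top == 0.0:
        return MotionFeature(mf=np.zeros(6), norm_constant=0.0, zero_motion=True)
    return MotionFeature(mf=peaks / top, norm_constant=top)


def features_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-clip, per-source motion features into a tidy table.

    Each row dict needs ``clip_id``, ``source`` and a :class:`MotionFeature`
    under ``feature``.  Columns MF_1..MF_3, MF_5..MF_7 follow the analysed
    segment labels.
    """
    out = []
    for row in rows:
        feat: MotionFeature = row["feature"]
        rec = {"clip_id": row["clip_id"], "source": row["source"]}
        for seg, val in zip(ANALYSED_SEGMENTS, feat.mf):
            rec[f"MF_{seg}"] = val
        rec["norm_constant"] = feat.norm_constant
        rec["zero_motion"] = feat.zero_motion
        out.append(rec)
    return pd.DataFrame(out)
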