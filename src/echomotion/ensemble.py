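"""Segment-wise IoU scoring and weighted fusion of motion features.

Different segmentation sources are good at different parts of the wall, so
their motion features are fused with per-segment weights derived from
segment-wise Intersection-over-Union against a reference segmentation:

    W[i, s] = M_i[s] / sum_j M_j[s]          (weights per segment)
    fused[s] = sum_i MF_i[s] * W[i, s]       (weighting ensemble, WE)

The unweighted elementwise mean (averaging ensemble, AE) is the baseline.
Segment-wise IoU regions are defined on the reference geometry: every
pixel of the union of the two masks is assigned to the segment of its
nearest sampled reference boundary point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .features import MotionFeature
from .geometry import SegmentPartition
from .simulate import MaskSequence

ANALYSED_SEGMENTS = (1, 2, 3, 5, 6, 7)


@dataclass
class SegmentScore:
    """Segment-wise and whole-wall IoU of one source against a reference."""

    M: np.ndarray               # (6,) per-segment IoU in [0, 1]; NaN = undefined
    full_iou: float
    source: str
    calibration_id: str = ""


@dataclass
class WeightSet:
    """Per-segment fusion weights, one row per source."""

    W: np.ndarray               # (n_sources, 6), columns sum to 1
    sources: tuple[str, ...]


def segment_iou(
    pred: MaskSequence,
    ref: MaskSequence,
    ref_partitions: list[SegmentPartition],
) -> SegmentScore:
    """Pooled whole-wall and per-segment IoU of ``pred`` against ``ref``.

    Counts are pooled (summed) over frames before the ratio is taken.
    Per-segment counts use the frames for which a reference partition
    exists; each union pixel joins the segment of its nearest sampled
    reference boundary point in that frame.  A segment whose pooled union
    is empty gets IoU NaN (recorded as missing).
    """
    if pred.frames.shape != ref.frames.shape:
        raise ValueError("pred and ref must have identical shape and frame count")
    inter_full = int((pred.frames & ref.frames).sum())
    union_full = int((pred.frames | ref.frames).sum())
    full_iou = inter_full / union_full if union_full else float("nan")

    inter = np.zeros(6)
    union = np.zeros(6)
    for part in ref_partitions:
        k = part.frame_index
        p, r = pred.frames[k], ref.frames[k]
        ys, xs = np.nonzero(p | r)
        if ys.size == 0:
            continue
        pts = part.points.reshape(-1, 2)                  # (6N, 2) as (x, y)
        seg_of_sample = np.repeat(np.arange(6), part.n_samples)
        _, nearest = cKDTree(pts).query(np.column_stack((xs, ys)))
        seg = seg_of_sample[nearest]
        both = (p[ys, xs] & r[ys, xs]).astype(bool)
        inter += np.bincount(seg[both], minlength=6)
        union += np.bincount(seg, minlength=6)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(union > 0, inter / np.maximum(union, 1), np.nan)
    if np.isnan(M).any():
        warnings.warn(f"{pred.source}: segment(s) with empty union; IoU undefined")
    return SegmentScore(M=M, full_iou=full_iou, source=pred.source)


def ensemble_weights(scores: list[SegmentScore]) -> WeightSet:
    """Per-segment weights proportional to each source's segment score.

    Missing (NaN) scores are excluded from a segment's normalization and
    get weight 0 there.  A segment scored zero (or missing) by every
    source falls back to uniform weights with a warning.
    """
    if not scores:
        raise ValueError("need at least one source score")
    M = np.vstack([s.M for s in scores]).astype(float)
    M = np.where(np.isnan(M), 0.0, M)
    col = M.sum(axis=0)
    W = np.empty_like(M)
    for s in range(6):
        if col[s] > 0:
            W[:, s] = M[:, s] / col[s]
        else:
            warnings.warn(f"segment {ANALYSED_SEGMENTS[s]}: all-zero scores; uniform weights")
            W[:, s] = 1.0 / len(scores)
    return WeightSet(W=W, sources=tuple(s.source for s in scores))


def accumulate_features(features: list[MotionFeature], weights: WeightSet) -> np.ndarray:
    """Weighting-ensemble fusion: per-segment convex combination of features."""
    if len(features) != weights.W.shape[0]:
        raise ValueError("feature list and weight rows must match")
    F = np.vstack([f.mf for f in features])
    return (F * weights.W).sum(axis=0)


def average_ensemble(features: list[MotionFeature]) -> np.ndarray:
    """Averaging-ensemble baseline: unweighted elementwise mean."""
    if not features:
        raise ValueError("need at least one feature")
    return np.vstack([f.mf for f in features]).mean(axis=0)
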