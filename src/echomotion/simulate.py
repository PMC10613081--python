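"""Synthetic A4C left-ventricular wall phantoms.

Generates multi-frame binary masks of the LV myocardium as seen in an
apical four-chamber view: a horseshoe-shaped annulus (two concentric arcs
sharing a basal opening at the mitral plane) that contracts inward over one
cardiac cycle.  Motion is radial with a half-sine time profile; each of the
seven standard wall segments carries its own inward-motion amplitude, and
myocardial-infarction (MI) clips reduce the amplitude of one or more
segments (hypokinesia).  Pseudo-segmenters corrupt the ground-truth masks
with segment-specific boundary noise, standing in for the variable regional
accuracy of real segmentation networks.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter1d

#: Segment labels of the seven-segment A4C wall model, ordered along the
#: arc from the left basal corner to the right basal corner.  Label 4 is
#: the apical cap, which carries no analysed motion feature.
SEGMENT_LABELS = (1, 2, 3, 4, 5, 6, 7)
ANALYSED_SEGMENTS = (1, 2, 3, 5, 6, 7)
_ANALYSED_SPAN_INDEX = (0, 1, 2, 4, 5, 6)  # span position of each analysed segment

_N_ARC = 512  # dense samples along the wall arc used for rasterization


class PhantomGeometryError(ValueError):
    """Raised when phantom parameters describe a self-intersecting wall."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic LV-wall clip.

    Amplitudes are inward endocardial displacements in pixels for the six
    analysed segments (1, 2, 3, 5, 6, 7 in arc order); the apical cap moves
    with the mean amplitude of its two neighbours so the boundary stays
    geometrically plausible.
    """

    image_size: tuple[int, int] = (96, 96)
    n_frames: int = 25
    endo_radius: float = 26.0
    wall_thickness: float = 8.0
    opening_angle: float = 80.0
    base_amplitudes: tuple[float, ...] = (6.0,) * 6
    lesion_segments: frozenset[int] = frozenset()
    lesion_factor: float = 0.12
    noise: float = 0.0
    frame_period: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.endo_radius <= 0:
            raise PhantomGeometryError("endo_radius must be positive")
        if self.wall_thickness < 2:
            raise PhantomGeometryError("wall_thickness must be >= 2 px")
        if self.wall_thickness > self.endo_radius:
            raise PhantomGeometryError(
                "wall_thickness exceeds endo_radius: wall would self-intersect"
            )
        if not 0 < self.opening_angle < 180:
            raise PhantomGeometryError("opening_angle must lie in (0, 180) degrees")
        if not 0 <= self.lesion_factor <= 1:
            raise PhantomGeometryError("lesion_factor must lie in [0, 1]")
        if len(self.base_amplitudes) != 6:
            raise PhantomGeometryError("base_amplitudes must have 6 entries")
        if max(self.base_amplitudes) >= self.endo_radius - 2:
            raise PhantomGeometryError("motion amplitude too large for endo_radius")
        if not set(self.lesion_segments) <= set(ANALYSED_SEGMENTS):
            raise PhantomGeometryError(
                f"lesion_segments must be a subset of {ANALYSED_SEGMENTS}"
            )
        if self.n_frames < 1:
            raise PhantomGeometryError("n_frames must be >= 1")


@dataclass(frozen=True)
class SegmenterProfile:
    """Corruption profile of one pseudo-segmenter.

    ``per_segment_error`` holds boundary-perturbation standard deviations in
    pixels for the six analysed segments; ``dropout_prob`` is the per-frame
    probability of locally eroding the wall to a sliver.
    """

    name: str
    per_segment_error: tuple[float, ...] = (0.0,) * 6
    dropout_prob: float = 0.0
    jitter_frac: float = 0.35
    motion_damping: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.per_segment_error) != 6:
            raise ValueError("per_segment_error must have 6 entries")
        if min(self.per_segment_error) < 0:
            raise ValueError("per_segment_error must be non-negative")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must lie in [0, 1]")
        if not 0 <= self.jitter_frac <= 1:
            raise ValueError("jitter_frac must lie in [0, 1]")
        if self.motion_damping < 0:
            raise ValueError("motion_damping must be non-negative")

    @property
    def is_identity(self) -> bool:
        return max(self.per_segment_error) == 0 and self.dropout_prob == 0


@dataclass
class MaskSequence:
    """T binary frames of the LV wall for one clip from one source."""

    frames: np.ndarray  # (T, H, W) uint8, values {0, 1}
    clip_id: str
    source: str
    frame_period: float = 0.04

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.uint8)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if not np.isin(self.frames, (0, 1)).all():
            raise ValueError("mask frames must be binary")
        if not self.frames.any(axis=(1, 2)).all():
            raise ValueError("every frame needs at least one foreground pixel")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ClipTruth:
    """Ground-truth mask sequence plus the analytic boundary that made it.

    The dense radius fields let tests compare extracted boundaries against
    exact coordinates and let :func:`corrupt_sequence` perturb the boundary
    without re-measuring it from pixels.
    """

    masks: MaskSequence
    amplitudes: np.ndarray          # (6,) per analysed segment, after lesion
    lesion_segments: tuple[int, ...]
    center: tuple[float, float]     # (x, y) pixel coordinates
    phi: np.ndarray                 # (n_arc,) wall angles, left corner -> right
    r_endo: np.ndarray              # (T, n_arc) endocardial radius field
    r_epi: np.ndarray               # (T, n_arc) epicardial radius field

    def endo_points(self, frame: int) -> np.ndarray:
        """Exact (x, y) endocardial coordinates along the arc at ``frame``."""
        cx, cy = self.center
        r = self.r_endo[frame]
        return np.column_stack((cx + r * np.cos(self.phi), cy + r * np.sin(self.phi)))


def _span_of_arc_fraction(u: np.ndarray) -> np.ndarray:
    """Seven-span index (0..6) of arc fractions ``u`` in [0, 1]."""
    return np.minimum((u * 7).astype(int), 6)


def _amplitude_profile(spec: PhantomSpec) -> np.ndarray:
    """Per-span (7,) inward amplitudes with lesions applied.

    The apical cap (span 3) takes the mean of its post-lesion neighbours.
    """
    analysed = np.asarray(spec.base_amplitudes, dtype=float).copy()
    for seg in spec.lesion_segments:
        analysed[ANALYSED_SEGMENTS.index(seg)] *= spec.lesion_factor
    spans = np.empty(7)
    spans[list(_ANALYSED_SPAN_INDEX)] = analysed
    spans[3] = 0.5 * (analysed[2] + analysed[3])  # cap between segments 3 and 5
    return spans


_TRANSITION_SIGMA = 8.0  # arc samples (~1.5% of arc): width of inter-segment blending


def _dense_segment_profile(values7: np.ndarray, n: int = _N_ARC) -> np.ndarray:
    """Per-arc-sample profile of a per-span quantity, blended at span edges.

    The myocardium deforms continuously, so per-segment amplitudes (and
    error levels) are blended over a narrow transition band instead of
    jumping at segment borders; segment interiors keep their exact value.
    """
    u = np.linspace(0.0, 1.0, n)
    dense = np.asarray(values7, dtype=float)[_span_of_arc_fraction(u)]
    return gaussian_filter1d(dense, _TRANSITION_SIGMA, mode="nearest")


def _wall_angles(opening_angle: float, n: int = _N_ARC) -> np.ndarray:
    """Wall angles from the left basal corner over the apex to the right.

    Angles are measured from the +x axis with y pointing down (image rows),
    so the basal gap is centred on the downward direction.
    """
    gap = np.deg2rad(opening_angle)
    start = np.pi / 2 + gap / 2
    return start + np.linspace(0.0, 2 * np.pi - gap, n)


def _smooth_unit_noise(rng: np.random.Generator, n: int, sigma: float = 8.0) -> np.ndarray:
    """Smooth correlated noise along the arc, rescaled to unit variance."""
    x = gaussian_filter1d(rng.standard_normal(n), sigma, mode="nearest")
    sd = x.std()
    return x / sd if sd > 0 else x


class _RadialGrid:
    """Cached polar coordinates of every pixel center about a fixed origin."""

    def __init__(self, center: tuple[float, float], shape: tuple[int, int]):
        cx, cy = center
        ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
        dx, dy = xs - cx, ys - cy
        self.r = np.sqrt(dx * dx + dy * dy).ravel()
        self.angle = np.arctan2(dy, dx).ravel()  # (-pi, pi]
        self.shape = shape


def rasterize_wall(
    center: tuple[float, float],
    phi: np.ndarray,
    r_in: np.ndarray,
    r_out: np.ndarray,
    shape: tuple[int, int],
    grid: _RadialGrid | None = None,
) -> np.ndarray:
    """Fill the region between two radial boundary curves as a binary mask.

    The wall is star-shaped about ``center``, so a pixel belongs to it iff
    its angle falls inside the wall span and its radius lies between the
    boundary fields interpolated at that angle.
    """
    if grid is None:
        grid = _RadialGrid(center, shape)
    # map pixel angles into the [phi[0], phi[0] + 2*pi) branch
    a = np.mod(grid.angle - phi[0], 2 * np.pi) + phi[0]
    span = (a >= phi[0]) & (a <= phi[-1])
    lo = np.interp(a, phi, r_in)
    hi = np.interp(a, phi, r_out)
    inside = span & (grid.r >= lo) & (grid.r <= hi)
    return inside.reshape(shape).astype(np.uint8)


def simulate_clip(spec: PhantomSpec, mi: bool = False, clip_id: str = "clip") -> ClipTruth:
    """Generate one ground-truth clip.

    ``mi`` is a consistency check only: an MI clip must carry at least one
    lesioned segment in its spec and a non-MI clip none.  Every endocardial
    point moves inward by ``amplitude(segment) * sin(pi * t / (T - 1))`` —
    one contraction-relaxation cycle per clip.
    """
    if mi and not spec.lesion_segments:
        raise ValueError("MI clip requires at least one lesioned segment")
    if not mi and spec.lesion_segments:
        raise ValueError("non-MI clip must not carry lesions")

    h, w = spec.image_size
    center = (w / 2.0, h / 2.0)
    phi = _wall_angles(spec.opening_angle)
    amp = _dense_segment_profile(_amplitude_profile(spec))

    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames)
    phase = np.sin(np.pi * t / (spec.n_frames - 1)) if spec.n_frames > 1 else np.zeros(1)

    r_endo = np.empty((spec.n_frames, _N_ARC))
    r_epi = np.empty_like(r_endo)
    base_epi = spec.endo_radius + spec.wall_thickness
    for k in range(spec.n_frames):
        jitter_in = jitter_out = 0.0
        if spec.noise > 0:
            jitter_in = spec.noise * _smooth_unit_noise(rng, _N_ARC)
            jitter_out = spec.noise * _smooth_unit_noise(rng, _N_ARC)
        r_endo[k] = spec.endo_radius - amp * phase[k] + jitter_in
        r_epi[k] = np.maximum(base_epi + jitter_out, r_endo[k] + 1.0)

    grid = _RadialGrid(center, (h, w))
    frames = np.stack(
        [
            rasterize_wall(center, phi, r_endo[k], r_epi[k], (h, w), grid=grid)
            for k in range(spec.n_frames)
        ]
    )
    analysed = _amplitude_profile(spec)[list(_ANALYSED_SPAN_INDEX)]
    return ClipTruth(
        masks=MaskSequence(frames, clip_id=clip_id, source="gt", frame_period=spec.frame_period),
        amplitudes=analysed,
        lesion_segments=tuple(sorted(spec.lesion_segments)),
        center=center,
        phi=phi,
        r_endo=r_endo,
        r_epi=r_epi,
    )


def _profile_rng(profile: SegmenterProfile, clip_id: str) -> np.random.Generator:
    # independent, reproducible stream per (profile, clip)
    mix = zlib.crc32(clip_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng((profile.seed, mix))


def _measure_radii(mask: np.ndarray, center: tuple[float, float], phi: np.ndarray):
    """Inner/outer wall radius along each ray from ``center`` (NaN = no wall)."""
    h, w = mask.shape
    r_max = float(np.hypot(h, w)) / 2.0
    radii = np.arange(1.0, r_max, 0.5)
    cx, cy = center
    xs = np.rint(cx + radii[None, :] * np.cos(phi)[:, None]).astype(int)
    ys = np.rint(cy + radii[None, :] * np.sin(phi)[:, None]).astype(int)
    inside = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
    hit = np.zeros_like(inside)
    hit[inside] = mask[ys[inside], xs[inside]] > 0
    any_hit = hit.any(axis=1)
    first = hit.argmax(axis=1)
    last = hit.shape[1] - 1 - hit[:, ::-1].argmax(axis=1)
    r_in = np.where(any_hit, radii[first], np.nan)
    r_out = np.where(any_hit, radii[last], np.nan)
    return r_in, r_out


def corrupt_sequence(
    gt: MaskSequence,
    profile: SegmenterProfile,
    truth: ClipTruth | None = None,
) -> MaskSequence:
    """Apply a pseudo-segmenter's corruption to a ground-truth sequence.

    Boundary radius fields are perturbed with smooth noise whose standard
    deviation varies per segment, then re-rasterized so the output stays a
    valid binary mask.  With ``truth`` supplied the analytic radius fields
    are perturbed directly; otherwise they are measured from the pixels by
    ray casting.  A profile with zero error and zero dropout returns the
    input frames unchanged.
    """
    if profile.is_identity:
        return MaskSequence(gt.frames.copy(), gt.clip_id, profile.name, gt.frame_period)

    shape = gt.frames.shape[1:]
    if truth is not None:
        center, phi = truth.center, truth.phi
        r_in_all, r_out_all = truth.r_endo.copy(), truth.r_epi.copy()
    else:
        from .geometry import cavity_centroid  # local import to avoid cycle

        center = cavity_centroid(gt.frames[0])
        phi = _wall_angles_from_mask(gt.frames[0], center)
        pairs = [_measure_radii(f, center, phi) for f in gt.frames]
        r_in_all = np.stack([p[0] for p in pairs])
        r_out_all = np.stack([p[1] for p in pairs])
        # fill rare gap angles by interpolation along the arc
        for arr in (r_in_all, r_out_all):
            for row in arr:
                bad = np.isnan(row)
                if bad.any():
                    row[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(~bad), row[~bad])

    n = phi.size
    u = np.linspace(0.0, 1.0, n)
    err6 = np.asarray(profile.per_segment_error, dtype=float)
    err7 = np.empty(7)
    err7[list(_ANALYSED_SPAN_INDEX)] = err6
    err7[3] = 0.5 * (err6[2] + err6[3])
    err_u = _dense_segment_profile(err7, n)

    rng = _profile_rng(profile, gt.clip_id)
    grid = _RadialGrid(center, shape)
    frames = np.empty_like(gt.frames)
    # segmentation-model errors are largely systematic: a static per-clip
    # bias field plus a small per-frame jitter (fraction ``jitter_frac``
    # of the total error s.d.); redrawing the full error every frame
    # would wreck any displacement signal, which real models do not do
    jf = profile.jitter_frac
    bias_scale = np.sqrt(max(1.0 - jf**2, 0.0))
    # the systematic bias is a large-scale offset (very smooth along the
    # arc): it costs overlap accuracy but barely distorts arc length,
    # whereas the jitter lives at a finer spatial scale
    bias_in = bias_scale * _smooth_unit_noise(rng, n, sigma=32.0)
    bias_out = bias_scale * _smooth_unit_noise(rng, n, sigma=32.0)
    # where a model is inaccurate it also under-tracks wall motion: the
    # estimated boundary regresses toward its temporal mean in proportion
    # to the local error level (apparent hypokinesia on weak segments)
    damp_u = np.minimum(profile.motion_damping * err_u, 0.9)
    r_in_mean = r_in_all.mean(axis=0)
    for k in range(gt.n_frames):
        state_in = bias_in + jf * _smooth_unit_noise(rng, n)
        state_out = bias_out + jf * _smooth_unit_noise(rng, n)
        r_in = (1.0 - damp_u) * r_in_all[k] + damp_u * r_in_mean + err_u * state_in
        r_out = r_out_all[k] + err_u * state_out
        r_out = np.maximum(r_out, r_in + 1.0)
        if profile.dropout_prob > 0 and rng.random() < profile.dropout_prob:
            # local under-segmentation: thin the wall over a small window
            u0 = rng.uniform(0.05, 0.95)
            width = rng.uniform(0.01, 0.04)
            win = np.abs(u - u0) < width / 2
            r_in[win] += 0.6 * (r_out[win] - r_in[win])
        frame = rasterize_wall(center, phi, r_in, r_out, shape, grid=grid)
        if not frame.any():  # keep the sequence valid under extreme corruption
            frame = gt.frames[k].copy()
        frames[k] = frame
    return MaskSequence(frames, gt.clip_id, profile.name, gt.frame_period)


def _wall_angles_from_mask(mask: np.ndarray, center: tuple[float, float]) -> np.ndarray:
    """Angular grid spanning the wall arc of an arbitrary horseshoe mask."""
    probe = np.linspace(0.0, 2 * np.pi, 1440, endpoint=False)
    r_in, _ = _measure_radii(mask, center, probe)
    hit = ~np.isnan(r_in)
    if hit.all() or not hit.any():
        raise ValueError("mask has no basal opening; cannot span the wall arc")
    # rotate so the gap is contiguous, then take the hit run
    gap_start = int(np.flatnonzero(~hit)[0])
    order = np.roll(np.arange(probe.size), -gap_start)
    run = order[hit[order]]
    angles = np.unwrap(probe[run])
    return np.linspace(angles[0], angles[-1], _N_ARC)


@dataclass(frozen=True)
class CohortSpec:
    """Study-level parameters for a synthetic cohort."""

    n_mi: int = 72
    n_non_mi: int = 37
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    max_lesions: int = 3
    amplitude_cv: float = 0.10       # clip-to-clip global amplitude scatter
    segment_amplitude_cv: float = 0.06
    boundary_noise: float = 0.3      # px jitter on every ground-truth boundary

    def __post_init__(self) -> None:
        if self.n_mi < 1 or self.n_non_mi < 1:
            raise ValueError("cohort needs at least one clip per class")


@dataclass
class CohortClip:
    """One simulated clip with its ground truth and per-source corruptions."""

    clip_id: str
    label: int  # 1 = MI, 0 = non-MI
    truth: ClipTruth
    corrupted: dict[str, MaskSequence]


def generate_cohort(
    cohort: CohortSpec,
    profiles: list[SegmenterProfile],
    seed: int,
) -> list[CohortClip]:
    """Simulate a labelled cohort in memory.

    MI clips receive 1..max_lesions randomly chosen lesioned segments;
    non-MI clips receive none.  Per-clip amplitude scatter emulates
    physiological variation between subjects.  Fully reproducible from
    ``seed``.
    """
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("segmenter profile names must be unique")
    rng = np.random.default_rng(seed)
    labels = np.array([1] * cohort.n_mi + [0] * cohort.n_non_mi)
    rng.shuffle(labels)
    clips: list[CohortClip] = []
    for i, label in enumerate(labels):
        clip_id = f"clip{i:04d}"
        scale = rng.normal(1.0, cohort.amplitude_cv)
        seg_scale = rng.normal(1.0, cohort.segment_amplitude_cv, size=6)
        amps = np.clip(
            np.asarray(cohort.phantom.base_amplitudes) * scale * seg_scale, 0.5, None
        )
        lesions: frozenset[int] = frozenset()
        if label == 1:
            k = int(rng.integers(1, cohort.max_lesions + 1))
            lesions = frozenset(rng.choice(ANALYSED_SEGMENTS, size=k, replace=False).tolist())
        spec = replace(
            cohort.phantom,
            base_amplitudes=tuple(amps),
            lesion_segments=lesions,
            noise=cohort.boundary_noise,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        truth = simulate_clip(spec, mi=bool(label), clip_id=clip_id)
        corrupted = {
            p.name: corrupt_sequence(truth.masks, p, truth=truth) for p in profiles
        }
        clips.append(CohortClip(clip_id, int(label), truth, corrupted))
    return clips


def write_cohort(clips: list[CohortClip], out_dir) -> pd.DataFrame:
    """Write mask stacks as multipage TIFFs plus a manifest CSV.

    Returns the manifest.  Frames are stored 8-bit with foreground 255.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seen: set[str] = set()
    rows = []
    for clip in clips:
        if clip.clip_id in seen:
            raise ValueError(f"duplicate clip_id {clip.clip_id!r}")
        seen.add(clip.clip_id)
        row: dict[str, object] = {
            "clip_id": clip.clip_id,
            "label": clip.label,
            "lesion_segments": ";".join(map(str, clip.truth.lesion_segments)),
        }
        gt_path = out / f"{clip.clip_id}__gt.tif"
        tifffile.imwrite(gt_path, clip.truth.masks.frames * 255)
        row["path_gt"] = gt_path.name
        for name, seq in clip.corrupted.items():
            p = out / f"{clip.clip_id}__{name}.tif"
            tifffile.imwrite(p, seq.frames * 255)
            row[f"path_{name}"] = p.name
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_mask_stack(path, clip_id: str, source: str) -> MaskSequence:
    """Read a multipage TIFF mask stack written by :func:`write_cohort`."""
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return MaskSequence((frames > 0).astype(np.uint8), clip_id, source)


def simulate_cohort(
    n_mi: int,
    n_non_mi: int,
    cohort: CohortSpec | None = None,
    profiles: list[SegmenterProfile] | None = None,
    seed: int = 0,
    out_dir=None,
) -> pd.DataFrame:
    """Generate a cohort and write it to ``out_dir``; returns the manifest."""
    base = cohort or CohortSpec()
    base = replace(base, n_mi=n_mi, n_non_mi=n_non_mi)
    clips = generate_cohort(base, profiles or [], seed)
    if out_dir is None:
        raise ValueError("out_dir is required to write mask stacks")
    return write_cohort(clips, out_dir)


#: Weak-segment index sets (into the six analysed segments) dealt to
#: successive pseudo-segmenters.  Weak spots sit on the mid-wall segments
#: (2, 3, 5, 6) — the basal segments anchor the arc corners and damping
#: them distorts the whole arc-length correspondence.  The first two sets
#: are disjoint, so a two-source ensemble covers every segment.
WEAK_SETS = [(1, 2), (3, 4), (1, 4), (2, 3), (1, 3), (2, 4)]


def complementary_profiles(
    n_sources: int,
    hard_error: float = 2.5,
    base_error: float = 0.5,
    dropout_prob: float = 0.02,
    jitter_frac: float = 0.35,
    motion_damping: float = 0.1,
    seed: int = 0,
) -> list[SegmenterProfile]:
    """Pseudo-segmenters that are each weak on a different part of the wall.

    Source ``k`` carries ``hard_error`` boundary noise on its own weak
    segment set (see :data:`WEAK_SETS`; the first two sources are weak on
    complementary halves of the wall) and ``base_error`` elsewhere — the
    regime in which each segmentation model has different weakest heart
    segments and an ensemble can cover the whole wall.
    """
    if n_sources < 1:
        raise ValueError("need at least one source")
    profiles = []
    for k in range(n_sources):
        err = [base_error] * 6
        for s in WEAK_SETS[k % len(WEAK_SETS)]:
            err[s] = hard_error
        profiles.append(
            SegmenterProfile(
                name=f"seg{k}",
                per_segment_error=tuple(err),
                dropout_prob=dropout_prob,
                jitter_frac=jitter_frac,
                motion_damping=motion_damping,
                seed=seed + 101 * k,
            )
        )
    return profiles
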