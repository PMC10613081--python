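# Methods

`echomotion` detects myocardial infarction (MI) from sequences of binary
left-ventricular (LV) wall masks in the apical four-chamber (A4C) view.
The pipeline has four stages: endocardial geometry, per-segment motion
features, IoU-weighted fusion of features from several segmentation
sources, and classical-classifier detection with an agreement-based
reliability analysis.  Because the package ships no imaging data and no
trained networks, a synthetic phantom module generates every input the
pipeline consumes; this note documents the model behind each stage, the
parameters that matter, and what the synthetic results do and do not show.

## Wall-motion model and feature definition

The LV wall in an A4C mask is a horseshoe; its inner edge (the
endocardium) moves inward during systole.  The boundary is an open arc
from the left basal corner over the apex to the right basal corner.  It is
cut into seven equal-arc-length segments; the apical cap (the fourth span)
shows no inward motion in this view and is excluded, leaving the six
analysed segments 1, 2, 3, 5, 6, 7.  Each retained segment is sampled with
N points at equal arc spacing (endpoints included), giving every frame the
same 6 x N grid of corresponding points anchored at the left corner.

For reference frame t_r (the first usable frame) and any other frame t,
the displacement of segment s is the mean L1 distance over its samples:

    d[s, t] = (1/N) * sum_n |x_n(t_r) - x_n(t)| + |y_n(t_r) - y_n(t)|

The motion feature is the per-segment maximum over the cycle, normalized
by the largest of the six maxima:

    MF[s] = max_t d[s, t] / max_s' max_t d[s', t]        MF in [0,1]^6

so a hypokinetic (infarcted) segment appears as a small entry.  If no
segment moves at all, the zero-motion guard returns the zero vector with a
flag instead of dividing by zero.  Two properties of this normalization
matter in practice: it makes the feature scale-free (probe depth, pixel
pitch and global contractility cancel), and it couples segments — any
process that inflates one segment's apparent peak displacement rescales
the other five.  The second property is the feature's main fragility and
is visible in the corruption experiments below.

## Fusion of multiple segmentation sources

Different segmentation models are good at different parts of the wall.
Given per-source motion features MF_i and a per-segment quality score
M_i in [0,1]^6 (segment-wise IoU against a reference segmentation), the
weighting ensemble (WE) fuses

    W[i, s] = M_i[s] / sum_j M_j[s],      fused[s] = sum_i MF_i[s] W[i, s]

and the averaging ensemble (AE) uses uniform weights.  The weights are
proportional — a segment scored 0.9 vs 0.7 yields weights 0.56/0.44 — so
WE departs from AE meaningfully only when segment scores are strongly
contrasted.  Segment-wise IoU regions are defined on the reference
geometry: every pixel of (prediction ∪ reference) joins the segment of its
nearest sampled reference boundary point, and counts are pooled over
frames before the ratio.  (Assigning only reference pixels would make the
within-region union equal the region and turn the statistic into recall;
the union-based assignment keeps it a true IoU.)

In the cross-validated experiment the scores M_i are recalibrated inside
each fold from the training clips only; a guard raises if a test clip
reaches the calibration set.

## Detection and reliability

Four off-the-shelf classifiers (SVM, logistic regression, decision tree,
k-nearest-neighbour) are compared under stratified 5-fold CV.
Hyperparameters come from an inner stratified 3-fold grid search scored by
F1: C in {0.01, 0.1, 10, 100} for SVM and LR, L1 vs L2 penalty for LR,
tree depth {5, 10, 25, unlimited} and split size {2, 5, 10} for DT, and
k in {2, 5, 10, 25, 50} for KNN.  Scale-sensitive models (SVM, LR, KNN)
are wrapped with a standardizer fitted on the training portion.  Reported
metrics are sensitivity, specificity, precision, F1 (beta = 1) and
accuracy, as fold means with s.d. and as pooled counts; denominator-zero
cases report 0 with a flag.

Reliability is Cohen's kappa between predictions of classifier variants on
a common held-out subset (20 items by default): the single-feature
scenario trains one variant per source, the ensemble-feature scenario one
variant per unordered source pair (WE-fused).  The summary is the mean of
pairwise kappas; when both raters are constant, kappa is defined as 1 if
they agree everywhere and 0 otherwise.  An expert scenario accepts
external rater labels.

## The phantom generator

Ground truth is a truncated annulus: two concentric arcs sharing a basal
opening (default 80 degrees), endocardial radius 26 px and wall thickness
8 px in a 96 x 96 frame, T = 25 frames per clip (one second at 25 fps,
one contraction-relaxation cycle).  Every endocardial point moves inward
by amplitude(segment) * sin(pi t / (T-1)); the epicardial arc stays fixed,
so the wall thickens during systole.  Per-segment amplitudes default to a
flat 6 px profile; amplitude transitions between segments are blended over
a narrow band (~1.5% of the arc) because myocardium deforms continuously,
and the apical cap moves with the mean of its two neighbours.  MI clips
multiply the amplitudes of 1-3 randomly chosen segments by the lesion
factor (default 0.12 — severe hypokinesia); non-MI clips have no lesion.
Per-clip realism comes from a global amplitude scale (CV 10%, which the
normalization cancels), per-segment amplitude jitter (CV 6%), and smooth
boundary jitter (0.3 px s.d.).  Cohort size defaults to 72 MI / 37 non-MI.

The flat amplitude profile is a deliberate simplification.  Under uniform
contraction the arc shrinks proportionally, so equal-arc-fraction sampling
tracks material points exactly and a lesion is the only source of
tangential slide; with a graded profile, healthy inter-segment amplitude
differences leak a few pixels of tangential displacement into every
segment and blur the lesion signature.  Real A4C motion is graded — the
phantom trades that realism for a construction in which the detection task
is unambiguously solvable from the feature definition.

## Pseudo-segmenters

Trained networks are replaced by corruption profiles applied to the
ground-truth boundary radius fields (re-rasterized afterwards, so outputs
stay valid masks).  Three mechanisms, all observed in real segmentation
models, are parameterized per profile:

- **Systematic bias** — a static, very smooth per-clip offset field
  (s.d. = `per_segment_error`, per segment).  It costs overlap accuracy
  (drives IoU down) but cancels in frame-to-frame displacement, and its
  large spatial scale barely distorts arc length.
- **Jitter** — a per-frame redrawn component, fraction `jitter_frac`
  (default 0.35) of the total error s.d.  Frame-correlated error is what
  lets displacement features survive realistic segmentation noise at all:
  a per-frame-independent error field of the same marginal magnitude
  destroys them.
- **Motion damping** — the estimated boundary regresses toward its
  temporal mean by min(`motion_damping` * error, 0.9): where a model is
  locally inaccurate it also under-tracks motion, producing apparent
  hypokinesia on its weak segments.

`dropout_prob` adds occasional local under-segmentation (the wall thinned
by 60% over a small window).  A profile with zero error and zero dropout
returns the input unchanged.  The default error levels of
`complementary_profiles` (0.5 px typical, 2.5 px on each source's weak
segments) were chosen so segment IoUs fall in the range published model
comparisons show (about 0.9 typical, about 0.7 for a model's worst
segment).

## The replication stress regime

The qualitative claims the package replicates on synthetic cohorts are:
(1) WE-fused features beat AE and each single source on detection F1, and
(2) WE variants agree with each other (kappa) more than single-source
variants do.  Both require a regime in which each source has unambiguous,
complementary weak segments.  The stress regime therefore corrupts each
source's weak mid-wall segment pair hard (5 px error, bias-dominant with
jitter fraction 0.1 and damping 0.3/px) so that a weak segment is
effectively blind for its source — its IoU drops to ~0.5, its motion
signal is damped away — while the basal segments, which anchor the arc
corners, stay accurate for every source.  Weak pairs rotate over the
mid-wall segments 2, 3, 5, 6 (the first two sources are weak on disjoint
pairs), and MI clips in these cohorts carry 1-2 lesioned segments, so a
source's blind spots regularly hide all of a clip's lesions from it.  A
single source then misses those clips, the fusions see every segment, and
WE recovers more per-segment contrast than AE on exactly the weak
segments.  Two honest caveats.  First, this corruption is deliberately
harsher than typical published per-segment IoU spreads: with milder,
noise-dominated corruption the proportional weights of the fusion rule
are nearly uniform and WE is indistinguishable from AE.  Second, even in
this regime the WE-minus-AE margin in F1 is small (about +0.01 to +0.03
per cohort) relative to the seed-to-seed spread of a 109-clip
cross-validation, so the ordering holds in most but not all replicates;
the replication tables report per-replicate fold-mean and pooled F1 so
the margin and its variability are both visible.

## Numerical choices

- Boundary extraction casts 540 rays (0.25 px radial step) from a point
  inside the cavity (wall-pixel centroid, falling back to the hull-based
  cavity centroid), takes the longest contiguous run of first hits, and
  runs two passes — a least-squares circle fit of the provisional trace
  re-centers the rays so corner points are sampled cleanly.  Steep or
  monotone radius ramps at the arc ends (rays grazing the radial cap faces
  of the wall) are trimmed; trace radii are lightly smoothed (sigma 2
  samples) to remove sub-pixel stair-steps that would inflate local arc
  length.  On analytic phantoms every trace point lands within ~1 px of
  the true inner arc; the geometry stage is translation-equivariant to
  within rasterization error.
- Degenerate frames (no cavity, closed boundary) are skipped with a
  warning by default; a clip with more than 50% degenerate frames is
  rejected.  The displacement reference is the first non-degenerate frame.
- Apex = trace point of maximal perpendicular distance to the corner-corner
  chord, ties to the smaller index; a straight trace is flagged degenerate.
- Masks are rasterized by an exact star-shaped radial test (pixel angle and
  radius against the interpolated boundary fields) rather than polygon
  filling.
- All randomness flows through explicit integer seeds; replicate seeds are
  spawned from one base seed, and every CLI command writes byte-identical
  outputs for a fixed seed.

## Problem sizes

Unit and property tests run on small phantoms (tiny cohorts, 4-8 frame
clips) in seconds.  The pattern-replication studies use the full study
conditions — cohorts of 109 clips (72 MI / 37 non-MI), T = 25 frames,
four pseudo-segmenters — over 20 seeded replicates in the test suite and
10 in the acceptance script, sizes chosen to keep a complete run on one
CPU in the tens of minutes.

## Limitations

- Only masks are modelled; there is no speckle, no B-mode texture, no
  DICOM ingestion, and no segmentation network training.
- The phantom is a truncated annulus with radial motion and a half-sine
  time profile; real LV motion includes longitudinal shortening, torsion
  and through-plane effects that index-correspondence sampling only
  approximates.
- The corruption model, while mechanistically motivated, is a stylization:
  conclusions about the fusion's benefit transfer to real segmenters only
  insofar as their errors are frame-correlated and regionally structured.
- The per-clip max normalization couples segments; a segmentation source
  with a grossly inflated apparent motion on one segment distorts its
  whole feature vector, which no per-segment weighting can undo.
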