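"""Phantom generator: geometry validity, determinism, corruption behaviour."""

import numpy as np
import pytest

from echomotion.ensemble import segment_iou
from echomotion.geometry import resample_sequence
from echomotion.simulate import (
    CohortSpec,
    MaskSequence,
    PhantomGeometryError,
    PhantomSpec,
    SegmenterProfile,
    complementary_profiles,
    corrupt_sequence,
    generate_cohort,
    simulate_clip,
    write_cohort,
)


class TestPhantomSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"endo_radius": 0.0},
            {"wall_thickness": 1.0},
            {"wall_thickness": 30.0, "endo_radius": 20.0},
            {"opening_angle": 0.0},
            {"opening_angle": 190.0},
            {"lesion_factor": 1.5},
            {"base_amplitudes": (1.0, 2.0)},
            {"lesion_segments": frozenset({4})},  # the apical cap is not analysed
        ],
    )
    def test_bad_geometry_rejected(self, kwargs):
        with pytest.raises((PhantomGeometryError, ValueError)):
            PhantomSpec(**kwargs)

    def test_label_lesion_consistency_enforced(self):
        with pytest.raises(ValueError):
            simulate_clip(PhantomSpec(), mi=True)
        with pytest.raises(ValueError):
            simulate_clip(
                PhantomSpec(lesion_segments=frozenset({2})), mi=False
            )


class TestSimulateClip:
    def test_zero_motion_gives_identical_frames(self, static_clip):
        frames = static_clip.masks.frames
        assert all(np.array_equal(frames[0], f) for f in frames[1:])

    def test_same_seed_bit_identical(self):
        spec = PhantomSpec(noise=0.5, seed=11)
        a = simulate_clip(spec, clip_id="a")
        b = simulate_clip(spec, clip_id="a")
        assert np.array_equal(a.masks.frames, b.masks.frames)

    def test_lesioned_segment_static_in_parametric_coordinates(self, lesioned_clip):
        """With lesion factor 0, segment-2 boundary points do not move while
        the other segments contract (checked on the analytic radius field)."""
        n = lesioned_clip.r_endo.shape[1]
        u = np.linspace(0, 1, n)
        # interior band of the second of seven spans, clear of the narrow
        # inter-segment blending zone
        seg2 = (u > 1 / 7 + 0.06) & (u < 2 / 7 - 0.06)
        seg1 = (u > 0.06) & (u < 1 / 7 - 0.06)
        mid = lesioned_clip.masks.n_frames // 2
        moved = lesioned_clip.r_endo[0] - lesioned_clip.r_endo[mid]
        assert np.abs(moved[seg2]).max() < 0.01
        assert moved[seg1].min() > 1.0

    def test_masks_are_valid_horseshoes(self, uniform_clip):
        frames = uniform_clip.masks.frames
        assert frames.dtype == np.uint8
        assert set(np.unique(frames)) <= {0, 1}
        assert frames.any(axis=(1, 2)).all()

    def test_amplitude_larger_than_radius_rejected(self):
        with pytest.raises(PhantomGeometryError):
            PhantomSpec(base_amplitudes=(30.0,) * 6)


class TestMaskSequenceInvariants:
    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            MaskSequence(np.full((2, 4, 4), 3, dtype=np.uint8), "c", "s")

    def test_rejects_empty_frame(self):
        frames = np.ones((2, 4, 4), dtype=np.uint8)
        frames[1] = 0
        with pytest.raises(ValueError):
            MaskSequence(frames, "c", "s")


class TestCorruptSequence:
    def test_identity_profile_returns_exact_copy(self, uniform_clip):
        prof = SegmenterProfile("id", per_segment_error=(0.0,) * 6)
        out = corrupt_sequence(uniform_clip.masks, prof, truth=uniform_clip)
        assert np.array_equal(out.frames, uniform_clip.masks.frames)
        assert out.source == "id"

    def test_deterministic_given_seed(self, uniform_clip):
        prof = SegmenterProfile("p", per_segment_error=(1.0,) * 6, seed=5)
        a = corrupt_sequence(uniform_clip.masks, prof, truth=uniform_clip)
        b = corrupt_sequence(uniform_clip.masks, prof, truth=uniform_clip)
        assert np.array_equal(a.frames, b.frames)

    def test_output_stays_binary_same_shape(self, uniform_clip):
        prof = SegmenterProfile("p", per_segment_error=(2.5,) * 6, dropout_prob=0.3, seed=2)
        out = corrupt_sequence(uniform_clip.masks, prof, truth=uniform_clip)
        assert out.frames.shape == uniform_clip.masks.frames.shape
        assert set(np.unique(out.frames)) <= {0, 1}

    def test_corruption_without_truth_matches_geometry(self, uniform_clip):
        """Measuring the radius fields from pixels (no analytic truth) gives
        a corruption of the same character as the analytic fast path."""
        prof = SegmenterProfile("p", per_segment_error=(1.5,) * 6, seed=3)
        out = corrupt_sequence(uniform_clip.masks, prof)
        ref_parts = resample_sequence(uniform_clip.masks)
        score = segment_iou(out, uniform_clip.masks, ref_parts)
        assert 0.5 < score.full_iou < 0.98

    def test_iou_monotone_in_error_level(self, uniform_clip):
        """Segment IoU decreases (in expectation) as corruption grows."""
        ref_parts = resample_sequence(uniform_clip.masks)
        means = []
        for err in (0.5, 1.5, 3.0):
            vals = []
            for seed in range(10):
                prof = SegmenterProfile(
                    "p", per_segment_error=(err,) * 6, jitter_frac=0.35, seed=seed
                )
                out = corrupt_sequence(uniform_clip.masks, prof, truth=uniform_clip)
                vals.append(segment_iou(out, uniform_clip.masks, ref_parts).M)
            means.append(np.nanmean(vals, axis=0))
        means = np.vstack(means)
        assert (np.diff(means, axis=0) < 0).all()

    def test_complementary_profiles_best_on_different_segments(self, uniform_clip):
        """Each source scores best (vs the other) on its own strong segments,
        the regime where different models win on different heart segments."""
        ref_parts = resample_sequence(uniform_clip.masks)
        profiles = complementary_profiles(2, seed=4)
        M = {}
        for p in profiles:
            out = corrupt_sequence(uniform_clip.masks, p, truth=uniform_clip)
            M[p.name] = segment_iou(out, uniform_clip.masks, ref_parts).M
        better0 = M["seg0"] > M["seg1"]
        hard0 = np.array(profiles[0].per_segment_error) > np.array(
            profiles[1].per_segment_error
        )
        hard1 = np.array(profiles[1].per_segment_error) > np.array(
            profiles[0].per_segment_error
        )
        assert (~better0[hard0]).all()  # seg0 loses where it is corrupted hard
        assert better0[hard1].all()     # and wins where seg1 is corrupted hard


class TestCohort:
    def test_cohort_size_and_labels(self, tmp_path):
        spec = CohortSpec(
            n_mi=5, n_non_mi=3, phantom=PhantomSpec(n_frames=6, image_size=(64, 64))
        )
        clips = generate_cohort(spec, complementary_profiles(2, seed=0), seed=1)
        assert len(clips) == 8
        for c in clips:
            if c.label == 1:
                assert len(c.truth.lesion_segments) >= 1
            else:
                assert c.truth.lesion_segments == ()
        manifest = write_cohort(clips, tmp_path)
        assert len(manifest) == 8
        assert set(manifest.columns) >= {"clip_id", "label", "path_gt", "path_seg0"}

    def test_zero_mi_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_mi=0, n_non_mi=3)

    def test_manifest_deterministic(self, tmp_path):
        spec = CohortSpec(
            n_mi=3, n_non_mi=2, phantom=PhantomSpec(n_frames=4, image_size=(64, 64))
        )
        a = generate_cohort(spec, [], seed=9)
        b = generate_cohort(spec, [], seed=9)
        for ca, cb in zip(a, b):
            assert ca.label == cb.label
            assert ca.truth.lesion_segments == cb.truth.lesion_segments
            assert np.array_equal(ca.truth.masks.frames, cb.truth.masks.frames)

    def test_duplicate_clip_ids_rejected(self, tmp_path):
        spec = CohortSpec(
            n_mi=1, n_non_mi=1, phantom=PhantomSpec(n_frames=3, image_size=(64, 64))
        )
        clips = generate_cohort(spec, [], seed=0)
        clips[1].clip_id = clips[0].clip_id
        with pytest.raises(ValueError):
            write_cohort(clips, tmp_path)
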