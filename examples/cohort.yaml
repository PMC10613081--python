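# Example cohort configuration for `echomotion simulate`.
# Sizes follow the study proportions (72 MI / 37 non-MI); two
# pseudo-segmenters are each weak on a different pair of mid-wall segments.
n_mi: 72
n_non_mi: 37
phantom:
  image_size: [96, 96]
  n_frames: 25
  endo_radius: 26.0
  wall_thickness: 8.0
  opening_angle: 80.0
  base_amplitudes: [6.0, 6.0, 6.0, 6.0, 6.0, 6.0]
  lesion_factor: 0.12
profiles:
  - name: segA
    per_segment_error: [0.5, 2.5, 2.5, 0.5, 0.5, 0.5]   # weak on segments 2, 3
    dropout_prob: 0.02
  - name: segB
    per_segment_error: [0.5, 0.5, 0.5, 2.5, 2.5, 0.5]   # weak on segments 5, 6
    dropout_prob: 0.02
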