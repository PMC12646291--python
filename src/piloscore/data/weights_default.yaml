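# Default factor weights for the additive severity score.
# Boundary conventions: BMI exactly 30 takes the high-side points,
# distance exactly 5 cm takes the low-side (higher-risk) points,
# a pit count of exactly 5 falls in the middle bin.
schema_version: 1
factors:
- name: bmi
  kind: threshold
  field: bmi
  threshold: 30.0
  points_low: 1
  points_high: 2
  boundary: high
- name: sex
  kind: categorical
  field: sex
  points:
    male: 2
    female: 1
- name: hairy_back
  kind: boolean
  field: hairy_back
  points_true: 2
  points_false: 1
- name: diabetes
  kind: boolean
  field: diabetes
  points_true: 3
  points_false: 1
- name: prior_recurrence
  kind: boolean
  field: prior_recurrence
  points_true: 3
  points_false: 1
- name: midline_pits
  kind: bins
  field: n_midline_pits
  bins:
  - {label: "<5", points: 2, upper: 5, inclusive: false}
  - {label: "5-10", points: 4, upper: 10, inclusive: true}
  - {label: ">10", points: 6}
- name: lateral_pits
  kind: boolean
  field: lateral_pits
  points_true: 3
  points_false: 1
- name: distance
  kind: threshold
  field: distance_to_anus_cm
  threshold: 5.0
  points_low: 3
  points_high: 1
  boundary: low
- name: prior_abscess
  kind: boolean
  field: prior_abscess
  points_true: 3
  points_false: 1
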