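# Prospective generative spec: marginal covariate prevalences from the
# whole-cohort distribution table; the outcome is drawn from a logistic
# link on the computed score, with the intercept calibrated to the
# observed 12.2% recurrence prevalence.
mode: prospective
n_total: 156
binary:
  male: 0.692
  diabetes: 0.135
  prior_recurrence: 0.167
  lateral_pits: 0.269
  hairy_back: 0.410
  distance_lt5: 0.244
  prior_abscess: 0.314
  wound_dehiscence: 0.167
pits: [0.532, 0.321, 0.147]
continuous:
  age: {marginal: [27.31, 6.48], lo: 18, hi: 45}
  bmi: {marginal: [29.12, 4.63], lo: 19.0, hi: 41.0}
  operative_time_min: {marginal: [44.42, 12.63], lo: 21.0, hi: 75.0}
  drain_removal_day: {marginal: [7.39, 1.34], lo: 7, hi: 14}
logistic:
  beta1: 0.8
  target_prevalence: 0.122
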