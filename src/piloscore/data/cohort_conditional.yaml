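# Outcome-conditional generative spec: prevalences and moments per outcome
# group, transcribed from the published two-group comparison of the 156
# patient cohort (137 without recurrence, 19 with recurrence).
mode: conditional
n_total: 156
n_recurrent: 19
binary:
  male: {p_not: 0.657, p_rec: 0.947}
  diabetes: {p_not: 0.080, p_rec: 0.526}
  prior_recurrence: {p_not: 0.109, p_rec: 0.579}
  postop_infection: {p_not: 0.0, p_rec: 0.158}
  lateral_pits: {p_not: 0.197, p_rec: 0.789}
  hairy_back: {p_not: 0.350, p_rec: 0.842}
  distance_lt5: {p_not: 0.168, p_rec: 0.789}
  prior_abscess: {p_not: 0.255, p_rec: 0.737}
  wound_dehiscence: {p_not: 0.167, p_rec: 0.167}
pits:
  p_not: [0.577, 0.343, 0.080]
  p_rec: [0.211, 0.158, 0.631]
continuous:
  age: {not: [27.29, 6.44], rec: [27.47, 6.88], lo: 18, hi: 45}
  bmi: {not: [28.61, 4.43], rec: [32.79, 4.52], lo: 19.0, hi: 41.0}
  operative_time_min: {not: [42.91, 11.77], rec: [55.32, 13.59], lo: 21.0, hi: 75.0}
  drain_removal_day: {not: [7.39, 1.34], rec: [7.39, 1.34], lo: 7, hi: 14}
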