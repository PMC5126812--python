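# Study-calibrated default cohort spec: 43 OI / 42 FD / 24 XLH adults,
# published age, sex and EQ-5D-5L response-level distributions, the
# calibrated bimodal utility mixture, and the published OI age couplings.
# Omitted keys (level_probs) fall back to the packaged fixture counts.
seed: 0
utility_mode: mixture
n_by_disease: {OI: 43, FD: 42, XLH: 24}
age_params:
  OI:  {mean: 40.4, sd: 14.4, low: 18, high: 70}
  FD:  {mean: 44.3, sd: 14.5, low: 18, high: 75}
  XLH: {mean: 46.3, sd: 16.3, low: 22, high: 78}
sex_female_prob: {OI: 0.77, FD: 0.69, XLH: 0.79}
vas_params:
  OI:  {mean: 69.4, sd: 21.4}
  FD:  {mean: 64.1, sd: 23.0}
  XLH: {mean: 60.8, sd: 26.9}
utility_mixture:
  weights: [0.45, 0.55]
  means: [0.45, 0.85]
  sds: [0.29, 0.12]
  bounds: [-0.285, 1.0]
couplings:
  OI:  {age_usual_activity: 0.39, age_vas: -0.42, utility_age_slope: -0.005}
  FD:  {}
  XLH: {}
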