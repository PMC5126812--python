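{
  "description": "Published summary values for the 109-person rare-bone-disease cohort; the synthetic pipeline is calibrated to these.",
  "utility_mean": {"OI": 0.656, "FD": 0.656, "XLH": 0.648, "Overall": 0.654},
  "utility_sd": {"OI": 0.283, "FD": 0.288, "XLH": 0.290, "Overall": 0.284},
  "vas_mean": {"OI": 69.4, "FD": 64.1, "XLH": 60.8},
  "vas_sd": {"OI": 21.4, "FD": 23.0, "XLH": 26.9},
  "fisher_p": {"MO": 0.775, "SC": 0.322, "UA": 1.000, "PD": 0.627, "AD": 0.100},
  "anova_utility_p": 0.993,
  "target_utility": 0.745,
  "mean_gain_base": 2.47,
  "control_total_qalys": 41,
  "treatment_total_qalys": 78,
  "gain_sd": 1.66,
  "sensitivity_gains": {"0.55": 1.83, "0.65": 2.15, "0.75": 2.47, "0.85": 2.79, "0.95": 3.11},
  "wtp_base_case": {"20000": 5742, "50000": 14355, "100000": 28709},
  "annual_cost_total_50k": 123561
}
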