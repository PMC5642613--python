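# Printed descriptors of the three study cohorts the synthetic fixtures
# emulate. These are documentation constants (cohort sizes, sex counts,
# the module size and its reported correlation range, the reported
# hazard ratio); the generators' default parameters mirror them.
study_cohorts:
  pan_cancer: {n_samples: 2158, n_entities: 163, n_hcc_samples: 45}
  validation: {n_patients: 242}
  resection:  {n_patients: 119, n_female: 26, n_male: 93}
module:
  size: 42
  cc_range: [0.56, 0.96]
  retained_in_validation: 10
reported_hr: {hr: 1.5, ci_low: 0.99, ci_high: 2.27}
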