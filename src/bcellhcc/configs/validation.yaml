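# Default validation-cohort fixture.
#
# Emulates an independent two-platform HCC cohort with paired tumor /
# non-tumor arrays and survival: 242 patients; the 42 discovery-module
# genes are present but only 10 remain co-regulated (retained) in this
# cohort; patients in the "high" half overexpress the retained genes in
# tumor tissue; survival is exponential with the LOW-expression group's
# hazard multiplied by true_hr (high expression is protective) and
# administrative censoring.
validation:
  n_patients: 242
  module_size: 42
  retained_coregulated_count: 10
  n_background_genes: 1000
  platforms:
    - {label: U133A2, loc: 0.0, scale: 1.0}
    - {label: HTU133A, loc: 0.5, scale: 1.15}
  overexpression_effect: 6.5   # log2 shift of retained genes, tumor vs non-tumor, high patients
  retained_within_cc: 0.914    # target pairwise CC of retained genes in tumor arrays
  high_fraction: 0.5
  true_hr: 1.5                 # hazard of low- vs high-expression group
  baseline_hazard: 0.0116      # per month, high group (median ~60 months)
  censor_time_months: 96.0
pipeline:
  cc_threshold: 0.8
  alpha: 0.05
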