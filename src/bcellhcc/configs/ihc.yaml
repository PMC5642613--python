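# Default immunohistochemistry fixture.
#
# Emulates a 119-patient resected-HCC cohort with manual B-cell counts
# (CD20, CD79a) in three regions -- tumor (Tu), infiltrative margin (Im),
# distant stroma (Sd) -- as mean/SEM pairs per marker and region
# (cells per high-power field). Counts are overdispersed: a shared
# patient-level gamma intensity (Gaussian-copula coupled across markers
# and regions through one latent B-cell factor) with Poisson field
# counts, so the mean of the three fields matches the configured mean
# and its cohort SEM. Survival hazard is linked to per-region high/low
# CD20 infiltration; immunoglobulin (Kappa/IgM) positivity is linked to
# Im-region infiltration.
ihc:
  n_patients: 119
  count_family: negative_binomial
  latent_corr: 0.6
  region_means:          # [mean, SEM] cells/HPF
    CD20:  {Tu: [8.0, 2.0],  Im: [65.0, 5.0], Sd: [25.0, 3.0]}
    CD79a: {Tu: [13.0, 3.0], Im: [62.0, 7.0], Sd: [23.0, 3.0]}
  survival_link:         # hazard ratio, high vs low infiltration (CD20-defined)
    Tu: 0.85
    Im: 0.5
    Sd: 1.6
  baseline_hazard: 0.01475   # per month; marginal median near 47 months
  censor_time_months: 120.0
  positivity_link:       # P(Kappa/IgM positive) per region given Im-high / Im-low
    p_high: {Tu: 0.8, Im: 0.85, Sd: 0.25}
    p_low:  {Tu: 0.1, Im: 0.15, Sd: 0.2}
  covariates:
    female_fraction: 0.2185
    age_mean: 65.0
    age_sd: 9.6
    t_stage_high_p: 0.4
    bridging_p: 0.2
    hep_b_p: 0.15
    hep_c_p: 0.25
    cirrhosis_p_im_high: 0.75
    cirrhosis_p_im_low: 0.45
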