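# Default pan-cancer discovery fixture.
#
# Emulates a multi-entity tumor expression compendium at desk scale:
# 542 genes x 300 samples with two planted co-regulated modules (the
# immunoglobulin-like 42-gene module plus a second, smaller network --
# real compendia carry many such networks and the 42-gene cluster was
# one of the largest) against uncorrelated background genes. One small
# entity is flagged HCC-like; modules are coherent across the cohort,
# so coherence also holds within that entity.
pan_cancer:
  n_background_genes: 475
  planted_modules:
    - size: 42
      within_cc: 0.9
    - size: 25
      within_cc: 0.9
  n_samples: 300
  n_entities: 20
  hcc_label: HCC
  hcc_n_samples: 6
  noise_sd: 1.0
pipeline:
  cc_threshold: 0.8
  k_range: [2, 10]
  select_by: kl
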