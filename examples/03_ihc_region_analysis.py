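"""Region-stratified B-cell count analysis of a simulated IHC cohort.

Generates the default resection-cohort fixture (119 patients; CD20 and
CD79a counts per high-power field in tumor (Tu), infiltrative margin
(Im) and distant stroma (Sd); survival linked to infiltration;
immunoglobulin positivity linked to the Im B-cell density) and runs the
region analysis: mean +/- SEM per region, region comparisons, mean-split
high/low survival, and Kappa/IgM positivity.
"""

import bcellhcc as bc

config = bc.IHCConfig.default()
cohort = bc.generate_ihc_cohort(config, seed=1)
report = bc.ihc_region_analysis(cohort.records, cohort.survival)

for marker in ("CD20", "CD79a"):
    print(f"{marker}:")
    for region in ("Tu", "Im", "Sd"):
        mean, sem, n = report.summary[marker][region]
        surv = report.survival[marker][region]
        print(f"  {region}: {mean:5.1f} +/- {sem:4.1f} cells/HPF   "
              f"high/low log-rank p = {surv.p:.4f} "
              f"({surv.assignment.n_high} high, "
              f"{surv.assignment.n_low} low)")
    p_im_tu = report.comparisons[marker][("Im", "Tu")][1]
    p_im_sd = report.comparisons[marker][("Im", "Sd")][1]
    print(f"  Im vs Tu p = {p_im_tu:.2g}, Im vs Sd p = {p_im_sd:.2g}")
# B cells concentrate at the infiltrative margin; a small log-rank p for
# the Im region with more deaths among low-infiltration patients is the
# survival benefit of marginal B-cell infiltration.

print("Kappa light chain positivity by Im infiltration:")
for region, block in report.positivity["kappa"].items():
    print(f"  {region}: {block['frac_positive_high']:.0%} of Im-high vs "
          f"{block['frac_positive_low']:.0%} of Im-low patients "
          f"(Fisher p = {block['p']:.2g})")

print("clinical covariates vs Im-high/low (p-values):")
for cov, p in report.clinical.items():
    print(f"  {cov}: {p:.3f}")
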