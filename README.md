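# bcellhcc

Immunoglobulin co-expression modules and B-cell infiltration survival
analysis for hepatocellular carcinoma (HCC) cohorts.

## The problem

Whether tumor-infiltrating B cells help or harm HCC patients has been
contested. One line of evidence links the two through gene expression:
in large pan-cancer expression compendia, immunoglobulin fragments form
a tightly co-regulated gene module; in independent HCC cohorts, patients
whose tumors overexpress that module survive longer; and in resected
tumors, B-cell counts at the infiltrative margin (the tissue band around
the tumor) stratify survival. `bcellhcc` implements this three-stage
analysis as a tested, reusable library, together with synthetic-data
generators that emulate each cohort so every stage can be exercised and
calibrated without access to the original microarray series or slide
counts.

## The methods at its core

1. **Module discovery.** On a gene-by-sample matrix (genes summarized,
   arrays Z-scored), compute all pairwise Pearson correlations CC, keep
   genes with at least one partner at |CC| > 0.8, cluster the survivors
   with complete linkage on the distance d = 1 − |CC|, choose the number
   of clusters k with the Krzanowski–Lai index
   KL(k) = |DIFF(k)/DIFF(k+1)|, DIFF(k) = (k−1)^(2/p) W(k−1) − k^(2/p) W(k)
   (maximized) and the Hubert–Levin C index
   C = (S − S_min)/(S_max − S_min) (minimized), and report each module
   with its within-module CC range.
2. **Cohort validation.** Quantile-normalize a two-platform tumor /
   non-tumor cohort, reduce to the module's gene cut-set, identify the
   genes that remain co-regulated there, double-standardize (gene- then
   array-wise), group arrays by complete-linkage clustering into high /
   low module-expression patients, describe per-gene tumor vs non-tumor
   differences (Welch t, rank-sum, fold change), and compare survival
   between groups: Kaplan–Meier curves, the log-rank test, and a
   proportional-hazards hazard ratio HR (partial likelihood, Efron
   ties, Wald 95% CI).
3. **IHC region statistics.** For manual B-cell counts (CD20, CD79a;
   three fields per region) in tumor (Tu), infiltrative margin (Im) and
   distant stroma (Sd): mean ± SEM per region, Mann–Whitney region
   comparisons, mean-split high/low dichotomization followed by
   log-rank survival tests, Pearson correlations between marker/region
   profiles, Fisher-exact clinical associations, and immunoglobulin
   (Kappa/IgM) positivity fractions by infiltration group.

The synthetic generators plant known structure (co-regulated modules,
a configurable true hazard ratio, count means/SEMs) and return truth
tables, so recovery of every downstream claim is measurable.

## Worked example

```sh
python examples/01_module_discovery.py
```

prints (seed 1):

```
cohort: 542 genes x 300 samples
67 genes pass the |CC|>0.8 filter; validity indices pick k_KL=2, k_C=2
  module 1: 42 genes, within-module CC 0.86-0.92
  module 2: 25 genes, within-module CC 0.88-0.92
largest module equals the planted 42-gene set: True
within-HCC stability (6 samples): median |CC| 0.90
```

Both validity indices agree on two modules; the largest recovered
module is exactly the planted 42-gene immunoglobulin-like module, and
its co-expression holds up inside the small HCC-like entity. Projecting
that module onto the validation cohort
(`python examples/02_survival_validation.py`) yields

```
retained co-regulated genes: 10 of 42
groups: 118 high / 124 low module expression
log-rank p = 0.0293
hazard ratio (low vs high) = 1.37 (95% CI 1.03-1.82)
agreement of cluster-derived groups with generator truth: 1.000
```

so patients with low module expression carry ~1.4× the death hazard of
high expressors in this replicate (configured truth 1.5), and the
unsupervised array grouping matches the generator's planted groups
exactly. `examples/03_ihc_region_analysis.py` and
`examples/04_normalization_transforms.py` demonstrate the remaining
stages the same way.

A thin CLI wraps the same functions
(`bcellhcc simulate | discover | validate | ihc`); every subcommand
takes `--seed` and writes plain TSV/CSV/JSON outputs.

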