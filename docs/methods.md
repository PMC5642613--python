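# Methods

This note documents the statistical procedures `bcellhcc` implements,
what the synthetic cohorts do and do not emulate, the numerical
conventions, and the design choices made where the analysis left room.

## 1. Module discovery

**Input.** A gene-by-sample log-scale expression matrix. When probe-level
data are supplied, probes are collapsed to genes by per-array averaging
over the probe→gene map; arrays can be Z-scored (mean 0, sample sd 1 per
array) beforehand. Sample (n−1) standard deviations are used throughout
the package; the choice is a convention, stated once here.

**Correlation filter.** Pairwise Pearson correlation (CC) over genes;
a gene is kept when at least one *other* gene exceeds the threshold
strictly (|CC| > 0.8 by default). Because the filter is per-gene
best-partner rather than per-pair, a module's internal CC range can
extend below the threshold. Absolute values are used so strongly
anti-correlated genes cluster together.

**Clustering.** Agglomerative complete linkage on d = 1 − |CC|.
The agglomeration is implemented directly so the tie rule is part of
the contract: among pairs at the minimal complete-linkage distance, the
pair whose clusters hold the smallest original item indices merges
first. On tie-free input this equals any textbook implementation (the
test suite checks equivalence against a brute-force oracle that rescans
all cluster pairs each step, including instances with deliberately tied
distances).

**Cluster count.** Two validity indices are evaluated over a k range
(default 2–10):

* Krzanowski–Lai: W_k is the total within-cluster sum of squared
  deviations from cluster centroids with genes as points and samples as
  the p features; DIFF(k) = (k−1)^(2/p) W_{k−1} − k^(2/p) W_k and
  KL(k) = |DIFF(k)/DIFF(k+1)|, maximized. Values with DIFF(k+1) = 0 are
  flagged undefined and excluded from the argmax.
* Hubert–Levin C: with S the sum of within-cluster pairwise distances,
  N_w the number of within-cluster pairs and S_min/S_max the sums of
  the N_w smallest/largest pairwise distances overall,
  C = (S − S_min)/(S_max − S_min), minimized; undefined when all
  pairwise distances are equal.

W_k is computed in expression space while the C index uses the
clustering distance itself: KL is a dispersion criterion, C a distance
criterion. When the two indices disagree the profile reports both and
the pipeline uses KL by default (an explicit choice; no tie-break is
inherent to the indices). Ties in either argmax go to the smaller k.

**Modules.** The tree is cut at the selected k; modules are indexed by
decreasing size and carry the (min, max) of their within-module pairwise
CC. Per-entity stability re-computes the within-module CC on one
entity's samples only (≥ 3 samples required).

## 2. Cohort validation

The validation stage projects a module onto an independent cohort of
paired tumor/non-tumor arrays measured on two platforms:

1. quantile normalization over the combined matrix (each value replaced
   by the mean of the values at its rank; ties within an array receive
   the mean of the reference values over the occupied rank positions —
   deterministic, limma-style);
2. reduction to the intersection of the cohort's genes with the module
   (misses logged);
3. identification of **retained** genes — module genes whose |CC| with
   at least one other module gene exceeds the threshold across tumor
   arrays. This operationalizes "still co-regulated in this cohort";
   no criterion for gene relevance was otherwise specified;
4. double standardization — every gene row to mean 0/sd 1, then every
   array column to mean 0/sd 1. The column pass is computed over the
   full reduced cohort matrix, not over the module genes alone: array
   centering over only a module's genes would subtract away any
   module-wide expression shift and make the groups of interest
   mathematically invisible. In the original design the reduced matrix
   spans the genes of all discovered clusters, which has the same
   effect; the package makes it explicit. The output satisfies the
   column contract exactly (the row contract is necessarily broken by
   the second pass);
5. array grouping — complete-linkage clustering of arrays on Euclidean
   distance over the standardized retained genes, cut at k = 2 (the
   analysis produces exactly two survival groups). The cluster whose
   tumor arrays have the larger mean module expression on the
   pre-standardization scale is labeled "high"; each patient inherits
   the label of their tumor array. Significance of per-gene
   overexpression is reported (Welch t, rank-sum, fold change on the
   linear scale with logFC = log2) but does not gate the grouping;
6. survival — Kaplan–Meier curves per group, the log-rank test, and a
   Cox hazard ratio with the *low*-expression group as the exposed
   category, so a protective module yields HR > 1 for low vs high, the
   direction in which such results are conventionally reported.

Fold changes are ratios of linear-scale means (inputs are unlogged with
the matrix's declared log base, 2 by default), so a constant shift of c
on the log2 scale gives logFC = c.

## 3. Survival and count statistics

* **Kaplan–Meier** and the **log-rank test** wrap lifelines (events
  processed before censorings at tied times; the statistic is the usual
  (O−E)²/V chi-square with 1 df). Curves are exported as step-function
  tables, not images.
* **Cox hazard ratio** is implemented in-package for the single binary
  covariate the analyses need: Newton iteration on the partial
  likelihood, stopping at |gradient| < 1e-8 (max 100 iterations), with
  Efron tie handling by default and Breslow behind a flag; Wald 95% CI
  on the log scale. A group without events makes the partial likelihood
  monotone; this raises a dedicated error rather than returning a
  diverged estimate. The implementation agrees with lifelines'
  CoxPHFitter to ~1e-6 on tied and untied data (tested).
* **Mann–Whitney U** uses the exact null distribution when
  n_a·n_b ≤ 400 and the pooled sample is tie-free, otherwise the normal
  approximation with tie and continuity corrections (scipy). The exact
  branch is tested against full enumeration of rank arrangements.
* **Mean ± SEM** with SEM = sd/√n (undefined at n = 1, flagged).
* **Mean-split dichotomization**: strictly above the cohort mean →
  "high", at or below → "low". Equality at the mean is assigned low;
  the boundary had to be fixed and the conservative side was chosen.
* **Region analysis** (per marker): region means ± SEM; Im–Tu, Im–Sd,
  Tu–Sd comparisons with the unpaired Mann–Whitney test by default —
  regions are paired within patients, and a paired sign-rank
  alternative is available behind `paired_regions=True`, but the
  unpaired test is what the descriptive convention calls for; per-region
  mean-split followed by log-rank; Pearson correlations among all
  marker×region count profiles; clinical covariates vs the Im split
  via Fisher's exact test (binary) or Mann–Whitney (continuous) — the
  choice of a 2×2 exact test is this package's, no test being otherwise
  specified; Kappa/IgM positivity fractions per region compared between
  Im-high and Im-low patients by Fisher's exact test. Patients missing
  a region for a marker are excluded from that marker's analysis and
  reported.

## 4. Synthetic cohorts

The generators produce data with the statistical structure each stage
assumes, at desk scale, with truth tables. All are deterministic given
a seed; one `numpy` Generator drives each cohort.

**Pan-cancer discovery fixture** (default 542 genes × 300 samples,
20 entities with a 6-sample HCC-like entity, ~2% of samples). Module
co-expression is induced by one shared latent factor per module with
equal loadings; the loading for a target correlation r is
√(r/(1−r))·σ, so the expected pairwise CC is loading²/(loading²+σ²).
Two modules are planted — 42 genes and 25 genes, both at r = 0.9 —
against 475 independent background genes. Two modules rather than one
is deliberate: real compendia carry many co-regulated networks, and
with a single planted module the post-filter gene set *is* the module,
so any k ≥ 2 partition would split it and "recover the module as the
largest cluster" would be unattainable by construction. Modules are
coherent across all entities (so coherence inside the HCC entity
follows); background genes are independent, so at 300 samples their
largest |CC| stays far below the 0.8 filter.

**Validation fixture** (default 242 patients, paired tumor/non-tumor
arrays, two platforms with location/scale offsets, 42 module genes of
which 10 retained, 1000 background genes). Retained genes carry an
overexpression shift of 6.5 log2 units in the tumor arrays of the
"high" half of patients plus a small shared per-array factor; the two
together give the configured within-tumor pairwise CC of ≈ 0.91. The
bimodal shift carrying most of the correlation is intentional:
immunoglobulin transcript abundance tracks B-cell/plasma-cell content
and spans orders of magnitude between infiltrated and non-infiltrated
tissue, and it is exactly this bimodality that makes unsupervised array
grouping recover the patient groups. The background gene count matters
too: quantile normalization over very few genes distorts the
distribution tails where the shifted values live, attenuating their
correlations. Survival is exponential with the low group's hazard
multiplied by the true HR (default 1.5 — high expression protective)
and administrative censoring at 96 months with a baseline hazard of
0.0116/month (median ≈ 60 months in the high group, ~26% censored
overall).

**IHC fixture** (default 119 patients, markers CD20/CD79a, regions
Tu/Im/Sd with means ± SEM of 8±2, 65±5, 25±3 and 13±3, 62±7, 23±3
cells/HPF). Counts are overdispersed: with sd = SEM·√n, a patient-level
gamma intensity with variance sd² − mean/3 feeds three Poisson field
counts, so the three-field mean has exactly the configured mean and
cohort SEM (negative-binomial family; a moment-matched lognormal
intensity is available for underdispersed settings, and a target with
sd² ≤ mean/3 is rejected with that suggestion). Intensities are coupled
across markers and regions through one latent infiltration factor via a
Gaussian copula (loading 0.6), which produces the expected positive
cross-marker/region correlations and ties everything downstream to one
biological quantity. Survival hazard multiplies per-region hazard
ratios for high infiltration (defaults 0.85 Tu, 0.5 Im, 1.6 Sd — margin
infiltration protective, stromal accumulation adverse, tumor-core
neutral-to-favorable) on a baseline of 0.01475/month (marginal median
≈ 47 months, ≈ 40% five-year survival under exponential decay), with
administrative censoring at 120 months. Kappa/IgM positivity is
Bernoulli with region-specific probabilities conditional on Im-high
status (e.g. 0.85 vs 0.15 in the Im region); cirrhosis is the one
clinical covariate linked to infiltration (0.75 vs 0.45), the others
are independent.

**What the fixtures do not emulate.** Probe-level microarray noise,
batch effects beyond a two-platform location/scale offset, non-
proportional hazards, informative censoring, inter-observer counting
variability, and the real cohort sizes of the discovery compendium
(thousands of arrays). Passing tests therefore demonstrate that the
pipeline recovers planted structure under its stated assumptions — not
that those assumptions hold in any particular public dataset.

## 5. Numerical conventions and degenerate inputs

* Sample (n−1) sd everywhere; correlations clipped to [−1, 1].
* Quantile normalization is idempotent on tie-free data (tested to
  1e-10); with ties, re-application can move values slightly because
  tie-averaging changes the reference.
* Constant genes/arrays raise named errors at the pass where they
  become degenerate rather than producing NaNs. A 2×2 matrix is
  inherently degenerate for double standardization (after row
  standardization both rows are (−s, s), so columns are constant);
  the smallest meaningful input is 3×3.
* Zscore-by-array is exactly invariant to affine rescaling of any
  single array. Double standardization is *not* (rescaling one column
  changes every row's mean and sd in the first pass); no such
  invariance is claimed or tested for it.
* Cluster-count selection needs partitions at k−1 and k+1, so the
  feasible KL range is [2, n−2].
* Monte-Carlo scales used by the test suite and the acceptance script
  (replicate counts of 50–1500, cohort sizes 119/242/300) are chosen so
  each check's Monte-Carlo error is small against its tolerance while
  the whole suite stays in the minutes range on one CPU.

## 6. Known limitations

* The Cox stage handles exactly one binary covariate; multivariable
  adjustment and competing risks are out of scope.
* The hazard-ratio estimator carries the usual finite-sample bias of
  partial likelihood (about +0.01 on the log scale at ~180 events);
  averages of raw HR estimates across replicates additionally include
  Jensen's term (≈ +2% here). Recovery checks are therefore phrased on
  the log scale.
* Array grouping assumes the two-group structure dominates the reduced
  matrix; with weak or absent overexpression the k = 2 cut of a noise
  cloud is arbitrary (by design — the generators expose this regime for
  testing).
* The survival endpoint is whatever the input table encodes; overall
  and recurrence-free survival are not distinguished.
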