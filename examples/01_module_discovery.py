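"""Discover co-expression modules in a simulated pan-cancer cohort.

Generates the default discovery fixture (542 genes x 300 samples, two
planted co-regulated modules among uncorrelated background genes), runs
the discovery pipeline (|CC|>0.8 partner filter, 1-|CC| complete-linkage
clustering, KL/C-index cluster-count selection) and compares the result
with the generator's truth table.
"""

import bcellhcc as bc

config = bc.PanCancerConfig.default()
cohort = bc.generate_pancancer_cohort(config, seed=1)
print(f"cohort: {cohort.matrix.n_genes} genes x "
      f"{cohort.matrix.n_samples} samples")

result = bc.run_discovery(cohort.matrix, cc_threshold=0.8,
                          k_range=(2, 10))
print(f"{len(result.filtered_genes)} genes pass the |CC|>0.8 filter; "
      f"validity indices pick k_KL={result.profile.k_kl}, "
      f"k_C={result.profile.k_c}")
for mod in result.modules:
    print(f"  module {mod.index}: {mod.size} genes, "
          f"within-module CC {mod.cc_min:.2f}-{mod.cc_max:.2f}")

planted = set(cohort.module_genes(1))
recovered = set(result.modules.largest.genes)
print(f"largest module equals the planted 42-gene set: "
      f"{recovered == planted}")

# the module stays coherent inside the small HCC-like entity
stab = bc.module_stability_in_subset(cohort.matrix,
                                     cohort.module_genes(1), "HCC")
print(f"within-HCC stability ({stab.n_samples} samples): median |CC| "
      f"{stab.abs_cc_median:.2f}")
# A median within-module correlation near the configured 0.9 in both
# the full cohort and the HCC subset is the signature of a module that
# is co-regulated across entities rather than an artifact of one.
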