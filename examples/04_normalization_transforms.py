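"""The expression-matrix transforms, shown on a toy two-platform matrix.

Builds a small probe-level matrix with a deliberate platform offset,
then applies each transform in the order the pipeline uses them:
probe-to-gene summarization, per-array Z-score, quantile normalization,
and the gene- then array-wise double standardization.
"""

import numpy as np
import pandas as pd

import bcellhcc as bc

rng = np.random.default_rng(0)
probes = [f"probe{i}" for i in range(8)]
samples = [f"s{j}" for j in range(6)]
X = rng.normal(8.0, 1.0, size=(8, 6))
X[:, 3:] = 0.5 + 1.3 * X[:, 3:]  # platform offset on arrays s3-s5
matrix = bc.ExpressionMatrix(pd.DataFrame(X, index=probes,
                                          columns=samples))

probe_map = {p: f"G{i // 2}" for i, p in enumerate(probes)}
genes = bc.summarize_genes(matrix, probe_map)
print(f"summarization: {matrix.n_genes} probes -> {genes.n_genes} genes "
      f"(two probes averaged per gene)")

z = bc.zscore_by_array(genes)
print("per-array Z-score: column means",
      np.round(z.to_numpy().mean(axis=0), 12),
      "sds", np.round(z.to_numpy().std(axis=0, ddof=1), 12))

qn = bc.quantile_normalize(genes)
col_means = qn.to_numpy().mean(axis=0)
print("quantile normalization: per-array means now identical:",
      np.round(col_means, 6))
# every array shares the same value distribution, so the platform
# location/scale offset is gone while within-array ranks are intact

ds = bc.double_standardize(genes)
print("double standardization: column means",
      np.round(ds.to_numpy().mean(axis=0), 12),
      "column sds", np.round(ds.to_numpy().std(axis=0, ddof=1), 12))
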