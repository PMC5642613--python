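"""Expression-matrix transforms.

The four transforms the analysis depends on: per-array Z-scoring,
probe-to-gene summarization, cross-platform quantile normalization, and
the gene-then-array double standardization applied before array
grouping. All standard deviations are sample (n-1) standard deviations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .matrix import ExpressionMatrix

log = logging.getLogger("bcellhcc")


def zscore_by_array(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each array (column) to mean 0, sample sd 1."""
    X = matrix.to_numpy()
    if X.shape[0] < 2:
        raise DegenerateInputError("z-score needs >= 2 genes per array")
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DegenerateInputError(
            f"zero-variance array(s): {[matrix.sample_ids[i] for i in zero[:5]]}"
        )
    Z = (X - X.mean(axis=0)) / sd
    return matrix.with_values(pd.DataFrame(Z, index=matrix.values.index,
                                           columns=matrix.values.columns))


def summarize_genes(matrix: ExpressionMatrix,
                    probe_map: dict) -> ExpressionMatrix:
    """Collapse probe-level rows to genes by per-array averaging.

    ``probe_map`` maps probe id -> gene id (many-to-one). Probes without
    a mapping are dropped; the count is logged.
    """
    probes = [p for p in matrix.gene_ids if p in probe_map]
    dropped = matrix.n_genes - len(probes)
    if not probes:
        raise DegenerateInputError(
            "no probe in the matrix is covered by the probe map"
        )
    if dropped:
        log.info("summarize_genes: dropped %d unmapped probes", dropped)
    values = matrix.values.loc[probes]
    genes = pd.Index([probe_map[p] for p in probes], name="gene_id")
    summarized = values.groupby(genes, sort=False).mean()
    # deterministic output order: first occurrence of each gene
    return matrix.with_values(summarized)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every array onto the common (mean-of-sorted) distribution.

    Each value is replaced by the across-array mean of the values at its
    rank; within-array rank order is preserved. Ties within an array all
    receive the mean of the reference values at the rank positions the
    tied group occupies.
    """
    X = matrix.to_numpy()
    n_genes, n_arrays = X.shape
    if n_arrays < 2:
        raise DegenerateInputError(
            "quantile normalization needs >= 2 arrays"
        )
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_arrays):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        ranked = reference.copy()
        # average reference over runs of tied values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        start = 0
        for stop in list(boundaries) + [n_genes]:
            if stop - start > 1:
                ranked[start:stop] = reference[start:stop].mean()
            start = stop
        out[order, j] = ranked
    return matrix.with_values(pd.DataFrame(out, index=matrix.values.index,
                                           columns=matrix.values.columns))


def double_standardize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Gene-wise then array-wise centering and scaling.

    Pass 1 standardizes every gene row (mean 0, sample sd 1); pass 2
    standardizes every array column of the pass-1 result. The output
    satisfies the column contract exactly; the row contract is generally
    broken again by pass 2.
    """
    X = matrix.to_numpy()
    row_sd = X.std(axis=1, ddof=1)
    zero = np.flatnonzero(row_sd == 0)
    if zero.size:
        raise DegenerateInputError(
            f"zero-variance gene(s): {[matrix.gene_ids[i] for i in zero[:5]]}"
        )
    X1 = (X - X.mean(axis=1, keepdims=True)) / row_sd[:, None]
    col_sd = X1.std(axis=0, ddof=1)
    zero = np.flatnonzero(col_sd == 0)
    if zero.size:
        raise DegenerateInputError(
            f"zero-variance array(s) after gene standardization: "
            f"{[matrix.sample_ids[i] for i in zero[:5]]}"
        )
    X2 = (X1 - X1.mean(axis=0)) / col_sd
    return matrix.with_values(pd.DataFrame(X2, index=matrix.values.index,
                                           columns=matrix.values.columns))
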