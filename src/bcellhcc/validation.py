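"""Module projection and survival stratification in an independent cohort.

The discovered immunoglobulin module is projected onto a two-platform
tumor/non-tumor cohort: quantile normalization over both platforms,
reduction to the module gene cut-set, identification of the genes that
remain co-regulated in this cohort, gene- then array-wise double
standardization, hierarchical grouping of arrays into two patient
groups (high / low module expression), per-gene tumor vs non-tumor
differential-expression descriptors, and Kaplan-Meier / log-rank / Cox
survival comparison of the two groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discovery import (CorrelationTable, DistanceTable,
                        hierarchical_cluster, pairwise_correlation)
from .errors import DegenerateInputError
from .matrix import ExpressionMatrix, TUMOR, NON_TUMOR
from .normalize import double_standardize, quantile_normalize
from .records import (GroupAssignment, SurvivalRecord, HIGH, LOW,
                      attach_groups)
from . import stats as st

log = logging.getLogger("bcellhcc")


def project_module(matrix: ExpressionMatrix,
                   module_genes) -> ExpressionMatrix:
    """Restrict the matrix to the intersection with the module genes."""
    present = [g for g in module_genes if g in matrix.values.index]
    missing = len(list(module_genes)) - len(present)
    if not present:
        raise DegenerateInputError(
            "no module gene is present in the cohort matrix"
        )
    if missing:
        log.info("project_module: %d of %d module genes present "
                 "(%d missing)", len(present), len(present) + missing,
                 missing)
    return matrix.subset_genes(present)


def retained_coregulated_genes(matrix: ExpressionMatrix, *,
                               threshold: float = 0.8,
                               tissue: str = TUMOR) -> list:
    """Module genes that stay co-regulated in this cohort.

    A gene is retained when its |CC| with at least one other module gene
    exceeds ``threshold`` across the cohort's ``tissue`` arrays. This
    operationalizes "also co-regulated in the independent cohort".
    """
    if matrix.annotations is not None and \
            "tissue" in matrix.annotations.columns:
        sub = matrix.subset_samples(matrix.samples_with(tissue=tissue))
    else:
        sub = matrix
    corr = pairwise_correlation(sub)
    a = np.abs(corr.values.copy())
    np.fill_diagonal(a, 0.0)
    keep = np.flatnonzero((a > threshold).any(axis=1))
    kept = [corr.gene_ids[i] for i in keep]
    log.info("retained co-regulated genes: %d of %d (|CC|>%g in %s arrays)",
             len(kept), matrix.n_genes, threshold, tissue)
    return kept


def group_arrays(standardized: ExpressionMatrix, k: int = 2, *,
                 raw: ExpressionMatrix | None = None) -> GroupAssignment:
    """Group arrays by complete-linkage clustering, label high/low.

    Euclidean distance over the (double-standardized) module genes; the
    tree is cut at ``k`` = 2. The cluster whose tumor arrays have the
    larger mean module expression on the pre-standardization scale
    (``raw``, if given) is labeled "high". Patients inherit the label of
    their tumor array when tissue annotations are present, otherwise
    every array is labeled directly.
    """
    if standardized.n_samples < 2:
        raise DegenerateInputError("array grouping needs >= 2 arrays")
    if k != 2:
        raise DegenerateInputError("survival stratification uses k = 2")
    X = standardized.to_numpy().T  # arrays as points
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=2))
    dend = hierarchical_cluster(
        DistanceTable(standardized.sample_ids, D))
    labels = dend.cut(k)
    if len(np.unique(labels)) < k:
        raise DegenerateInputError("a cluster is empty after the cut")

    scale = raw if raw is not None else standardized
    ann = standardized.annotations
    has_tissue = ann is not None and "tissue" in ann.columns
    sample_ids = standardized.sample_ids
    means = {}
    for lab in (0, 1):
        ids = [s for s, l in zip(sample_ids, labels) if l == lab]
        if has_tissue:
            tumor_ids = [s for s in ids
                         if ann.loc[s, "tissue"] == TUMOR]
            ids = tumor_ids or ids
        means[lab] = float(scale.values[ids].to_numpy().mean())
    high_lab = max(means, key=means.get)

    if has_tissue and "patient_id" in ann.columns:
        assignment = {}
        for s, lab in zip(sample_ids, labels):
            if ann.loc[s, "tissue"] == TUMOR:
                assignment[ann.loc[s, "patient_id"]] = \
                    HIGH if lab == high_lab else LOW
    else:
        assignment = {s: (HIGH if lab == high_lab else LOW)
                      for s, lab in zip(sample_ids, labels)}
    ga = GroupAssignment(assignment, "cluster_derived",
                         rule="complete-linkage (Euclidean, standardized "
                              "module genes) cut at k=2; higher mean "
                              "module expression -> high")
    log.info("group_arrays: %d high / %d low", ga.n_high, ga.n_low)
    return ga


@dataclass
class DifferentialExpressionRecord:
    """Per-gene tumor vs non-tumor descriptors."""

    gene_id: str
    t_statistic: float
    t_p: float
    rank_statistic: float
    rank_p: float
    fold_change: float      # linear scale
    log_fold_change: float  # base 2
    direction: str          # "up" (tumor higher) / "down" / "flat"


def describe_differential_expression(matrix: ExpressionMatrix,
                                     gene_id) -> DifferentialExpressionRecord:
    """Welch t, rank-sum, and (log) fold change for one gene.

    Fold change is the ratio of linear-scale means (values unlogged with
    the matrix's log base); the log fold change is its base-2 log.
    """
    from scipy import stats as sps
    if gene_id not in matrix.values.index:
        raise DegenerateInputError(f"gene {gene_id!r} not in matrix")
    tumor_ids = matrix.samples_with(tissue=TUMOR)
    normal_ids = matrix.samples_with(tissue=NON_TUMOR)
    if len(tumor_ids) < 2 or len(normal_ids) < 2:
        raise DegenerateInputError(
            "need >= 2 tumor and >= 2 non-tumor samples"
        )
    tv = matrix.values.loc[gene_id, tumor_ids].to_numpy(dtype=float)
    nv = matrix.values.loc[gene_id, normal_ids].to_numpy(dtype=float)
    t_res = sps.ttest_ind(tv, nv, equal_var=False)
    u, rank_p = st.mann_whitney(tv, nv)
    lin_t = np.power(matrix.log_base, tv)
    lin_n = np.power(matrix.log_base, nv)
    fc = float(lin_t.mean() / lin_n.mean())
    lfc = float(np.log2(fc))
    direction = "up" if lfc > 0 else ("down" if lfc < 0 else "flat")
    return DifferentialExpressionRecord(
        gene_id, float(t_res.statistic), float(t_res.pvalue),
        float(u), float(rank_p), fc, lfc, direction)


@dataclass
class ValidationResult:
    """Full output bundle of the validation stage."""

    assignment: GroupAssignment
    retained_genes: list
    km_high: st.KMCurve
    km_low: st.KMCurve
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: st.HazardRatioEstimate
    differential_expression: list

    def de_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.differential_expression])


def validate_module_survival(matrix: ExpressionMatrix, module_genes,
                             survival: list[SurvivalRecord], *,
                             cc_threshold: float = 0.8,
                             apply_quantile_normalization: bool = True
                             ) -> ValidationResult:
    """Run the whole validation stage.

    Quantile-normalize over both platforms, project the module, find the
    genes that stay co-regulated in this cohort, double-standardize
    (gene- then array-wise over the full reduced dataset, so a
    module-wide shift survives the array centering), group arrays on the
    retained genes into high/low patients, describe per-gene tumor vs
    non-tumor differences, then compare survival between the groups
    (Kaplan-Meier, log-rank, Cox hazard ratio of low vs high).
    """
    work = quantile_normalize(matrix) if apply_quantile_normalization \
        else matrix
    projected = project_module(work, module_genes)
    retained = retained_coregulated_genes(projected,
                                          threshold=cc_threshold)
    if len(retained) < 2:
        raise DegenerateInputError(
            f"only {len(retained)} module genes stay co-regulated; "
            f"cannot group arrays"
        )
    standardized = double_standardize(work).subset_genes(retained)
    assignment = group_arrays(standardized, 2,
                              raw=work.subset_genes(retained))

    de = [describe_differential_expression(projected, g)
          for g in projected.gene_ids]

    grouped = attach_groups(survival, assignment)
    missing = {r.patient_id for r in survival} - set(assignment.labels)
    if missing:
        log.info("validation survival: %d patients lack a group label",
                 len(missing))
    hi = [r for r in grouped if r.group == HIGH]
    lo = [r for r in grouped if r.group == LOW]
    if not hi or not lo:
        raise DegenerateInputError("a survival group is empty")
    chi2, p = st.logrank_test(hi, lo)
    hr = st.cox_hr(grouped, exposed=LOW)
    log.info("validation survival: log-rank p=%.4g, HR(low vs high)=%.3g "
             "(95%% CI %.3g-%.3g)", p, hr.hr, hr.ci_low, hr.ci_high)
    return ValidationResult(assignment, retained, st.km_estimate(hi),
                            st.km_estimate(lo), chi2, p, hr, de)
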