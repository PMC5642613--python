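"""Co-expression module discovery.

Pipeline: pairwise Pearson correlation over genes -> keep genes with at
least one partner at |CC| strictly above the threshold -> transform to
the distance d = 1 - |CC| -> complete-linkage agglomeration -> choose
the cluster count with the Krzanowski-Lai and Hubert-Levin C validity
indices -> extract modules (clusters) with their within-module CC range.

The agglomeration is implemented here rather than delegated so that the
tie-break is fully specified: among pairs at the minimal complete-linkage
distance the pair whose clusters contain the smallest original item
indices merges first. On tie-free distances the result coincides with
any textbook complete-linkage implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .matrix import ExpressionMatrix

log = logging.getLogger("bcellhcc")


# --------------------------------------------------------------------------
# correlation and distance tables
# --------------------------------------------------------------------------

@dataclass
class CorrelationTable:
    """Symmetric gene x gene Pearson correlation grid (diagonal 1)."""

    gene_ids: list
    values: np.ndarray

    def __post_init__(self):
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise DegenerateInputError("correlation grid shape mismatch")

    def pair(self, a, b) -> float:
        i, j = self.gene_ids.index(a), self.gene_ids.index(b)
        return float(self.values[i, j])

    def subset(self, gene_ids) -> "CorrelationTable":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return CorrelationTable(list(gene_ids),
                                self.values[np.ix_(idx, idx)].copy())


@dataclass
class DistanceTable:
    """Symmetric gene x gene distance grid d = 1 - |CC| (diagonal 0)."""

    gene_ids: list
    values: np.ndarray


def pairwise_correlation(matrix: ExpressionMatrix) -> CorrelationTable:
    """Full Pearson correlation table over genes (rows)."""
    X = matrix.to_numpy()
    if X.shape[1] < 3:
        raise DegenerateInputError("correlation needs >= 3 samples")
    sd = X.std(axis=1, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DegenerateInputError(
            f"constant gene(s): {[matrix.gene_ids[i] for i in zero[:5]]}"
        )
    cc = np.corrcoef(X)
    np.fill_diagonal(cc, 1.0)
    cc = np.clip(cc, -1.0, 1.0)
    return CorrelationTable(matrix.gene_ids, cc)


def filter_correlated_genes(corr: CorrelationTable,
                            threshold: float = 0.8) -> list:
    """Genes with at least one *other* gene at |CC| strictly > threshold."""
    if not 0 < threshold < 1:
        raise DegenerateInputError(f"threshold must be in (0,1), "
                                   f"got {threshold}")
    a = np.abs(corr.values.copy())
    np.fill_diagonal(a, 0.0)
    keep = np.flatnonzero((a > threshold).any(axis=1))
    kept = [corr.gene_ids[i] for i in keep]
    log.info("filter |CC|>%g: kept %d of %d genes", threshold, len(kept),
             len(corr.gene_ids))
    return kept


def correlation_distance(corr: CorrelationTable) -> DistanceTable:
    """d(i,j) = 1 - |CC(i,j)|."""
    d = 1.0 - np.abs(corr.values)
    np.fill_diagonal(d, 0.0)
    return DistanceTable(list(corr.gene_ids), d)


# --------------------------------------------------------------------------
# complete-linkage agglomeration
# --------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative merge tree.

    ``merges`` has one row per merge ``(a, b, height, size)`` in
    scipy convention: leaves are numbered ``0..n-1``, the cluster formed
    by merge ``m`` is ``n + m``.
    """

    ids: list
    merges: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def cut(self, k: int) -> np.ndarray:
        """Labels (0..k-1) of the partition into ``k`` clusters.

        Clusters are numbered by their smallest member's input position.
        """
        n = self.n_leaves
        if not 1 <= k <= n:
            raise DegenerateInputError(f"cannot cut {n} items into {k}")
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        members = {i: [i] for i in range(n)}
        node_root = list(range(n))  # root leaf for each node id
        for m in range(n - k):
            a, b, _, _ = self.merges[m]
            ra, rb = find(node_root[int(a)]), find(node_root[int(b)])
            parent[rb] = ra
            node_root.append(ra)
        roots = {}
        labels = np.empty(n, dtype=int)
        for i in range(n):
            r = find(i)
            if r not in roots:
                roots[r] = len(roots)
            labels[i] = roots[r]
        return labels


def hierarchical_cluster(dist: DistanceTable,
                         linkage: str = "complete") -> Dendrogram:
    """Complete-linkage agglomeration of a precomputed distance table."""
    if linkage != "complete":
        raise DegenerateInputError(f"unsupported linkage {linkage!r}")
    D0 = np.asarray(dist.values, dtype=float)
    n = D0.shape[0]
    if n < 2:
        raise DegenerateInputError("clustering needs >= 2 items")
    if not np.isfinite(D0).all():
        raise DegenerateInputError("non-finite distance")
    D = D0.copy()
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    node_of_slot = np.arange(n)  # current scipy node id held by each slot
    merges = np.zeros((n - 1, 4))
    sizes = np.ones(n, dtype=int)
    for m in range(n - 1):
        # masked copy so inactive slots never win
        masked = np.where(active[:, None] & active[None, :], D, np.inf)
        flat = int(np.argmin(masked))
        i, j = divmod(flat, n)
        if i > j:  # row-major argmin returns i<j for symmetric grids,
            i, j = j, i  # but guard anyway
        h = masked[i, j]
        merges[m] = (node_of_slot[i], node_of_slot[j], h,
                     sizes[i] + sizes[j])
        # complete linkage: new cluster distance = elementwise max
        D[i, :] = np.maximum(D[i, :], D[j, :])
        D[:, i] = D[i, :]
        D[i, i] = np.inf
        active[j] = False
        sizes[i] += sizes[j]
        node_of_slot[i] = n + m
    return Dendrogram(list(dist.gene_ids), merges)


# --------------------------------------------------------------------------
# cluster-count selection (KL and C indices)
# --------------------------------------------------------------------------

@dataclass
class ValidityProfile:
    """KL and C index values per candidate cluster count.

    ``kl[k]`` is NaN where the index is undefined (zero successor
    difference); ``k_kl`` maximizes KL, ``k_c`` minimizes C, ties broken
    toward the smaller count.
    """

    ks: list
    kl: dict
    c: dict
    k_kl: int
    k_c: int

    def selected(self, select_by: str = "kl") -> int:
        if select_by == "kl":
            return self.k_kl
        if select_by == "c":
            return self.k_c
        raise DegenerateInputError(f"unknown selector {select_by!r}")


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared deviations from centroids
    (items are rows of X)."""
    w = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        if len(pts) > 1:
            w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def _c_index(D: np.ndarray, labels: np.ndarray) -> float:
    """Hubert-Levin C: (S - S_min) / (S_max - S_min) with S the sum of
    within-cluster pairwise distances and S_min/S_max the sums of the
    N_w smallest/largest distances overall."""
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    all_d = D[iu]
    same = labels[iu[0]] == labels[iu[1]]
    n_w = int(same.sum())
    if n_w == 0:
        return np.nan
    s = float(all_d[same].sum())
    d_sorted = np.sort(all_d)
    s_min = float(d_sorted[:n_w].sum())
    s_max = float(d_sorted[-n_w:].sum())
    if s_max == s_min:
        raise DegenerateInputError(
            "C index undefined: all pairwise distances equal"
        )
    return (s - s_min) / (s_max - s_min)


def select_cluster_count(dendrogram: Dendrogram, dist: DistanceTable,
                         matrix: ExpressionMatrix,
                         k_range: tuple[int, int] = (2, 10)
                         ) -> ValidityProfile:
    """Evaluate KL and C over ``k_range`` and pick the count each favors.

    The Krzanowski-Lai dispersion W_k is computed in expression space
    (genes as points, samples as features, p = number of samples):
    DIFF(k) = (k-1)^(2/p) W_{k-1} - k^(2/p) W_k and
    KL(k) = |DIFF(k) / DIFF(k+1)|. The C index is computed on the
    clustering distance itself.
    """
    n = dendrogram.n_leaves
    kmin, kmax = k_range
    kmin = max(2, kmin)
    kmax = min(kmax, n - 2)  # KL(k) needs a (k+1)-partition with k+1 <= n-1
    if kmax < kmin:
        raise DegenerateInputError(
            f"k_range {k_range} infeasible for {n} items"
        )
    X = matrix.subset_genes(dendrogram.ids).to_numpy()
    p = X.shape[1]
    partitions = {k: dendrogram.cut(k) for k in range(kmin - 1, kmax + 2)}
    W = {k: _within_dispersion(X, lab) for k, lab in partitions.items()}

    def diff(k):
        return (k - 1) ** (2.0 / p) * W[k - 1] - k ** (2.0 / p) * W[k]

    ks = list(range(kmin, kmax + 1))
    kl, c = {}, {}
    for k in ks:
        d_next = diff(k + 1)
        kl[k] = np.nan if d_next == 0 else abs(diff(k) / d_next)
        c[k] = _c_index(dist.values, partitions[k])
    valid_kl = [k for k in ks if np.isfinite(kl[k])]
    if not valid_kl:
        raise DegenerateInputError("KL index undefined at every k")
    k_kl = min(valid_kl, key=lambda k: (-kl[k], k))
    k_c = min(ks, key=lambda k: (c[k], k))
    log.info("validity profile over k=%s: k_KL=%d, k_C=%d", k_range,
             k_kl, k_c)
    return ValidityProfile(ks, kl, c, k_kl, k_c)


# --------------------------------------------------------------------------
# module extraction and stability
# --------------------------------------------------------------------------

@dataclass
class Module:
    """One co-expression module: members plus the within-module CC range."""

    index: int
    genes: list
    cc_min: float | None
    cc_max: float | None

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class ModuleSet:
    modules: list

    @property
    def largest(self) -> Module:
        return self.modules[0]

    def __iter__(self):
        return iter(self.modules)

    def __len__(self):
        return len(self.modules)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"module": m.index, "gene_id": g}
                for m in self.modules for g in m.genes]
        return pd.DataFrame(rows)


def extract_modules(dendrogram: Dendrogram, k: int,
                    corr: CorrelationTable) -> ModuleSet:
    """Cut the tree at ``k`` clusters; modules are indexed by decreasing
    size (module 1 = largest). Singleton modules have an undefined CC
    range (None)."""
    labels = dendrogram.cut(k)
    order = {g: i for i, g in enumerate(corr.gene_ids)}
    groups = []
    for lab in np.unique(labels):
        genes = [dendrogram.ids[i] for i in np.flatnonzero(labels == lab)]
        groups.append(genes)
    groups.sort(key=lambda gs: (-len(gs), min(order[g] for g in gs)))
    modules = []
    for rank, genes in enumerate(groups, start=1):
        if len(genes) < 2:
            cc_min = cc_max = None
        else:
            idx = [order[g] for g in genes]
            sub = corr.values[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            pair_cc = sub[iu]
            cc_min, cc_max = float(pair_cc.min()), float(pair_cc.max())
        modules.append(Module(rank, genes, cc_min, cc_max))
    return ModuleSet(modules)


@dataclass
class StabilitySummary:
    """Within-module pairwise CC recomputed on one entity's samples."""

    entity: str
    n_samples: int
    cc_min: float
    cc_median: float
    cc_max: float
    abs_cc_median: float


def module_stability_in_subset(matrix: ExpressionMatrix, module_genes,
                               entity: str) -> StabilitySummary:
    """Recompute within-module correlation using only one entity's samples."""
    samples = matrix.samples_with(entity=entity)
    if len(samples) < 3:
        raise DegenerateInputError(
            f"entity {entity!r} has {len(samples)} samples; need >= 3"
        )
    sub = matrix.subset_genes(module_genes).subset_samples(samples)
    corr = pairwise_correlation(sub)
    iu = np.triu_indices(len(sub.gene_ids), k=1)
    cc = corr.values[iu]
    return StabilitySummary(entity, len(samples), float(cc.min()),
                            float(np.median(cc)), float(cc.max()),
                            float(np.median(np.abs(cc))))


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

@dataclass
class DiscoveryResult:
    modules: ModuleSet
    profile: ValidityProfile
    filtered_genes: list
    correlation: CorrelationTable
    k_used: int


def run_discovery(matrix: ExpressionMatrix, *, cc_threshold: float = 0.8,
                  k_range: tuple[int, int] = (2, 10),
                  select_by: str = "kl") -> DiscoveryResult:
    """Full discovery pipeline on an already gene-summarized matrix."""
    corr = pairwise_correlation(matrix)
    kept = filter_correlated_genes(corr, cc_threshold)
    if len(kept) < 4:
        raise DegenerateInputError(
            f"only {len(kept)} genes pass |CC|>{cc_threshold}; "
            f"cannot cluster"
        )
    sub_corr = corr.subset(kept)
    dist = correlation_distance(sub_corr)
    dend = hierarchical_cluster(dist)
    profile = select_cluster_count(dend, dist, matrix.subset_genes(kept),
                                   k_range)
    k = profile.selected(select_by)
    modules = extract_modules(dend, k, sub_corr)
    log.info("discovery: %d modules at k=%d; largest has %d genes",
             len(modules), k, modules.largest.size)
    return DiscoveryResult(modules, profile, kept, sub_corr, k)
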