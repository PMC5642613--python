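"""Module-discovery contracts: correlation filter, linkage oracle,
validity indices, planted-module recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest

import bcellhcc as bc
from bcellhcc.discovery import (DistanceTable, _c_index,
                                _within_dispersion)
from bcellhcc.errors import DegenerateInputError


def _matrix(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = [f"s{j}" for j in range(arr.shape[1])]
    return bc.ExpressionMatrix(pd.DataFrame(arr, index=genes,
                                            columns=samples))


class TestPairwiseCorrelation:
    def test_affine_and_sign(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        m = _matrix([x, 2 * x + 1, -x])
        cc = bc.pairwise_correlation(m)
        assert np.isclose(cc.pair("g0", "g1"), 1.0)
        assert np.isclose(cc.pair("g0", "g2"), -1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 12))
        cc = bc.pairwise_correlation(_matrix(X)).values
        for i in range(5):
            for j in range(5):
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert abs(cc[i, j] - r) < 1e-12

    def test_constant_gene_rejected_by_name(self):
        m = _matrix([[1, 2, 3], [4, 4, 4]])
        with pytest.raises(DegenerateInputError, match="g1"):
            bc.pairwise_correlation(m)


class TestFilterAndDistance:
    def test_partner_filter_keeps_both_ends(self):
        cc = np.full((4, 4), 0.1)
        np.fill_diagonal(cc, 1.0)
        cc[0, 1] = cc[1, 0] = 0.9
        table = bc.CorrelationTable(["a", "b", "c", "d"], cc)
        assert bc.filter_correlated_genes(table, 0.8) == ["a", "b"]

    def test_threshold_is_strict(self):
        cc = np.eye(2)
        cc[0, 1] = cc[1, 0] = 0.8
        table = bc.CorrelationTable(["a", "b"], cc)
        assert bc.filter_correlated_genes(table, 0.8) == []

    def test_distance_definition_and_symmetry(self):
        cc = np.array([[1.0, -1.0, 0.0],
                       [-1.0, 1.0, 0.5],
                       [0.0, 0.5, 1.0]])
        d = bc.correlation_distance(
            bc.CorrelationTable(["a", "b", "c"], cc))
        assert np.allclose(d.values, 1 - np.abs(cc))
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)


def brute_force_complete_linkage(D):
    """Rescan every cluster pair each step; lexicographic tie-break on
    the smallest original member indices."""
    n = D.shape[0]
    clusters = [[i] for i in range(n)]
    partitions = [[list(c) for c in clusters]]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(D[i, j] for i in clusters[a] for j in clusters[b])
            key = (d, min(clusters[a]), min(clusters[b]))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        clusters[a] = sorted(clusters[a] + clusters[b])
        del clusters[b]
        clusters.sort(key=min)
        partitions.append([list(c) for c in clusters])
    return partitions


def _partition_sets(labels):
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return {tuple(sorted(g)) for g in groups.values()}


class TestHierarchicalCluster:
    def test_two_tight_pairs_merge_first(self):
        D = np.array([[0, .1, 1, 1],
                      [.1, 0, 1, 1],
                      [1, 1, 0, .2],
                      [1, 1, .2, 0]], dtype=float)
        dend = bc.hierarchical_cluster(DistanceTable(list("abcd"), D))
        assert set(dend.merges[0, :2]) == {0, 1}
        assert set(dend.merges[1, :2]) == {2, 3}

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = 12
            D = np.abs(rng.normal(size=(n, n)))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            dend = bc.hierarchical_cluster(
                DistanceTable(list(range(n)), D))
            assert np.all(np.diff(dend.merges[:, 2]) >= -1e-12)

    @pytest.mark.parametrize("n", range(2, 9))
    def test_matches_bruteforce_oracle_random_instances(self, n):
        rng = np.random.default_rng(100 + n)
        for rep in range(30):
            D = rng.random((n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            dend = bc.hierarchical_cluster(
                DistanceTable(list(range(n)), D))
            oracle = brute_force_complete_linkage(D)
            for k in range(1, n + 1):
                ours = _partition_sets(dend.cut(k))
                theirs = {tuple(c) for c in oracle[n - k]}
                assert ours == theirs, (n, rep, k)

    @pytest.mark.parametrize("n", range(3, 8))
    def test_matches_bruteforce_oracle_with_tied_distances(self, n):
        rng = np.random.default_rng(200 + n)
        for rep in range(20):
            # few distinct values -> many exact ties
            D = rng.choice([0.25, 0.5, 1.0], size=(n, n))
            D = np.maximum(D, D.T)
            np.fill_diagonal(D, 0)
            dend = bc.hierarchical_cluster(
                DistanceTable(list(range(n)), D))
            oracle = brute_force_complete_linkage(D)
            for k in range(1, n + 1):
                assert _partition_sets(dend.cut(k)) == \
                    {tuple(c) for c in oracle[n - k]}, (n, rep, k)

    def test_single_item_rejected(self):
        with pytest.raises(DegenerateInputError):
            bc.hierarchical_cluster(
                DistanceTable(["a"], np.zeros((1, 1))))

    def test_non_finite_distance_rejected(self):
        D = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(DegenerateInputError):
            bc.hierarchical_cluster(DistanceTable(["a", "b"], D))


class TestValidityIndices:
    def _cluster(self, matrix):
        corr = bc.pairwise_correlation(matrix)
        dist = bc.correlation_distance(corr)
        return bc.hierarchical_cluster(dist), dist, corr

    def test_two_separated_clusters_select_k2(self):
        hits_kl = hits_c = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            f1, f2 = rng.normal(size=(2, 150))
            X = np.vstack([4 * f1 + rng.normal(size=(6, 150)),
                           4 * f2 + rng.normal(size=(6, 150))])
            m = _matrix(X)
            dend, dist, _ = self._cluster(m)
            profile = bc.select_cluster_count(dend, dist, m, (2, 6))
            hits_kl += profile.k_kl == 2
            hits_c += profile.k_c == 2
        assert hits_kl >= 0.95 * n_seeds
        assert hits_c >= 0.95 * n_seeds

    def test_c_index_bounded_on_random_data(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.normal(size=(15, 20)))
        dend, dist, _ = self._cluster(m)
        profile = bc.select_cluster_count(dend, dist, m, (2, 8))
        for k in profile.ks:
            assert 0.0 <= profile.c[k] <= 1.0

    def test_identical_points_degenerate(self):
        labels = np.array([0, 0, 1, 1])
        D = np.zeros((4, 4))
        with pytest.raises(DegenerateInputError):
            _c_index(D, labels)

    def test_kl_dispersion_matches_definition(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 5))
        labels = np.array([0, 0, 0, 1, 1, 2, 2, 2])
        w = 0.0
        for lab in (0, 1, 2):
            pts = X[labels == lab]
            w += ((pts - pts.mean(axis=0)) ** 2).sum()
        assert np.isclose(_within_dispersion(X, labels), w)


class TestModuleExtraction:
    def test_k_equals_n_gives_flagged_singletons(self):
        rng = np.random.default_rng(5)
        m = _matrix(rng.normal(size=(4, 10)))
        corr = bc.pairwise_correlation(m)
        dend = bc.hierarchical_cluster(bc.correlation_distance(corr))
        mods = bc.extract_modules(dend, 4, corr)
        assert len(mods) == 4
        assert all(mod.size == 1 and mod.cc_min is None for mod in mods)

    def test_cc_range_well_formed(self):
        rng = np.random.default_rng(6)
        m = _matrix(rng.normal(size=(8, 30)))
        corr = bc.pairwise_correlation(m)
        dend = bc.hierarchical_cluster(bc.correlation_distance(corr))
        for mod in bc.extract_modules(dend, 3, corr):
            if mod.size > 1:
                assert -1 <= mod.cc_min <= mod.cc_max <= 1

    def test_pipeline_invariant_to_gene_order(
            self, default_pancancer_config):
        coh = bc.generate_pancancer_cohort(default_pancancer_config, 3)
        res = bc.run_discovery(coh.matrix)
        rng = np.random.default_rng(0)
        perm = rng.permutation(coh.matrix.n_genes)
        shuffled = bc.ExpressionMatrix(
            coh.matrix.values.iloc[perm], coh.matrix.annotations)
        res2 = bc.run_discovery(shuffled)
        sets1 = {frozenset(m.genes) for m in res.modules}
        sets2 = {frozenset(m.genes) for m in res2.modules}
        assert sets1 == sets2


class TestModuleStability:
    def test_full_cohort_subset_is_identity(self, default_pancancer_config):
        coh = bc.generate_pancancer_cohort(default_pancancer_config, 4)
        genes = coh.module_genes(1)
        # an entity covering all samples
        ann = coh.matrix.annotations.copy()
        ann["entity"] = "ALL"
        m = bc.ExpressionMatrix(coh.matrix.values, ann)
        summ = bc.module_stability_in_subset(m, genes, "ALL")
        corr = bc.pairwise_correlation(m.subset_genes(genes))
        iu = np.triu_indices(len(genes), k=1)
        assert np.isclose(summ.cc_median, np.median(corr.values[iu]))
        assert summ.n_samples == m.n_samples

    def test_module_coherent_within_hcc_entity(
            self, default_pancancer_config):
        coh = bc.generate_pancancer_cohort(default_pancancer_config, 5)
        genes = coh.module_genes(1)
        summ = bc.module_stability_in_subset(coh.matrix, genes, "HCC")
        # background pair |CC| in a 6-sample subset is broad; the module
        # median must exceed the 95th percentile of background pairs
        bg = coh.truth.loc[coh.truth.module == 0, "gene_id"].tolist()[:60]
        sub = coh.matrix.subset_genes(bg).subset_samples(
            coh.matrix.samples_with(entity="HCC"))
        cc = bc.pairwise_correlation(sub).values
        iu = np.triu_indices(len(bg), k=1)
        assert summ.abs_cc_median > np.quantile(np.abs(cc[iu]), 0.95)

    def test_tiny_entity_rejected(self, small_matrix):
        with pytest.raises(DegenerateInputError):
            bc.module_stability_in_subset(small_matrix, ["G1", "G2"],
                                          "HCC")
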