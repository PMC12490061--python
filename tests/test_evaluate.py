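"""Clustering evaluation metrics and the clustering adapter."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
import scipy.sparse as sp

from mcfano import (
    ClusterLabels,
    CountMatrix,
    SimulationSpec,
    cluster_cells,
    enrichment_score,
    log_normalize,
    make_two_group_dataset,
    mean_group_purity,
    normalized_entropy,
    purity_pvalue,
    purity_score,
)


class TestLogNormalize:
    def test_hand_values(self):
        cm = CountMatrix(sp.csr_matrix(np.array([[1, 3], [2, 2]])))
        norm = np.asarray(log_normalize(cm).todense())
        assert norm[0, 0] == pytest.approx(np.log(2501))
        assert norm[0, 1] == pytest.approx(np.log(7501))

    def test_zero_count_stays_zero(self):
        cm = CountMatrix(sp.csr_matrix(np.array([[0, 4], [1, 1]])))
        assert np.asarray(log_normalize(cm).todense())[0, 0] == 0.0

    def test_zero_depth_cell_rejected(self):
        cm = CountMatrix(sp.csr_matrix(np.array([[0, 0], [1, 1]])))
        with pytest.raises(ValueError):
            log_normalize(cm)


class TestPurity:
    def test_concentrated_targets(self):
        labels = ClusterLabels(np.array([0, 0, 1, 1]), 2)
        res = purity_score(labels, np.array([True, True, False, False]))
        assert res.purity == 1.0 and res.best_cluster == 0

    def test_even_split(self):
        labels = ClusterLabels(np.array([0, 0, 1, 1]), 2)
        res = purity_score(labels, np.array([True, False, True, False]))
        assert res.purity == 0.5
        assert res.tied

    def test_direct_count(self):
        labels = ClusterLabels(np.array([0, 0, 1]), 2)
        res = purity_score(labels, np.array([True, True, True]))
        assert res.purity == pytest.approx(2 / 3)
        assert res.best_cluster == 0

    def test_tie_broken_toward_smaller_cluster(self):
        labels = ClusterLabels(np.array([0, 0, 0, 1, 1]), 2)
        res = purity_score(labels, np.array([True, False, False, True, False]))
        assert res.best_cluster == 1 and res.tied

    def test_zero_targets_rejected(self):
        with pytest.raises(ValueError):
            purity_score(ClusterLabels(np.array([0, 1]), 2), np.array([False, False]))

    def test_mean_group_purity_two_groups(self):
        labels = ClusterLabels(np.array([0, 0, 1, 1]), 2)
        assert mean_group_purity(labels, np.array([0, 0, 1, 1])) == 1.0


class TestPurityPvalue:
    def test_degenerate_cases(self):
        assert purity_pvalue(10, 3, 4, 0) == 1.0
        assert purity_pvalue(10, 3, 10, 3) == 1.0  # single all-embracing cluster

    def test_single_tail_term(self):
        # M=10, n=3 targets, N=4, k=3: C(3,3) C(7,1) / C(10,4) = 7/210
        assert purity_pvalue(10, 3, 4, 3) == pytest.approx(7 / 210)

    def test_inconsistent_arguments(self):
        with pytest.raises(ValueError):
            purity_pvalue(10, 3, 4, 5)

    def test_exhaustive_enumeration_small_populations(self):
        """Tail probability equals brute-force counting for all M <= 12."""
        for M in (5, 8, 12):
            for n in (1, 3, M // 2):
                for N in (2, M - 1):
                    for k in range(0, min(n, N) + 1):
                        hits = sum(
                            1
                            for pos in combinations(range(M), n)
                            if sum(p < N for p in pos) >= k
                        )
                        exact = hits / comb(M, n)
                        assert purity_pvalue(M, n, N, k) == pytest.approx(exact), (
                            M, n, N, k,
                        )


class TestEnrichment:
    def test_single_cluster_scores_one(self):
        norm = np.array([[1.0, 2.0], [3.0, 2.0]])
        labels = ClusterLabels(np.array([0, 0]), 1)
        scores, best = enrichment_score(norm, labels, 0)
        np.testing.assert_allclose(scores, [1.0])
        assert best == 1.0

    def test_ratio_of_means(self):
        norm = np.array([[6.0], [6.0], [0.0], [0.0], [0.0], [0.0]])
        labels = ClusterLabels(np.array([0, 0, 1, 1, 1, 1]), 2)
        scores, best = enrichment_score(norm, labels, 0)
        assert scores[0] == pytest.approx(3.0)
        assert best == pytest.approx(3.0)

    def test_unknown_gene_and_zero_mean(self):
        norm = np.zeros((3, 2))
        labels = ClusterLabels(np.array([0, 0, 1]), 2)
        with pytest.raises(KeyError):
            enrichment_score(norm, labels, "missing", gene_ids=["a", "b"])
        with pytest.raises(ValueError):
            enrichment_score(norm, labels, 0)


class TestNormalizedEntropy:
    def test_concentrated_is_zero(self):
        labels = ClusterLabels(np.array([0, 0, 1, 2]), 3)
        assert normalized_entropy(labels, np.array([True, True, False, False])) == 0.0

    def test_uniform_is_one(self):
        labels = ClusterLabels(np.array([0, 1, 2]), 3)
        assert normalized_entropy(labels, np.ones(3, bool)) == pytest.approx(1.0)

    def test_half_split_of_four_clusters(self):
        labels = ClusterLabels(np.array([0, 1, 2, 3]), 4)
        eta = normalized_entropy(labels, np.array([True, True, False, False]))
        assert eta == pytest.approx(np.log(2) / np.log(4))

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            normalized_entropy(ClusterLabels(np.zeros(3, int), 1), np.ones(3, bool))

    def test_opposes_purity_on_concentration(self):
        spread = ClusterLabels(np.array([0, 1, 2, 0, 1, 2]), 3)
        packed = ClusterLabels(np.array([0, 0, 0, 1, 1, 2]), 3)
        targets = np.array([True, True, True, False, False, False])
        assert purity_score(packed, targets).purity > purity_score(spread, targets).purity
        assert normalized_entropy(packed, targets) < normalized_entropy(spread, targets)


@pytest.fixture(scope="module")
def separable():
    spec = SimulationSpec(n_cells=300, n_genes=400, n_variable_genes=60, cv=0.7, seed=8)
    return make_two_group_dataset(spec)


class TestClusterCells:
    def test_deterministic_for_fixed_seed(self, separable):
        features = separable.counts.gene_ids[separable.variable_gene_mask]
        a = cluster_cells(separable.counts, features, resolution=0.5, seed=3)
        b = cluster_cells(separable.counts, features, resolution=0.5, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.n_clusters >= 1

    def test_true_features_separate_groups(self, separable):
        features = separable.counts.gene_ids[separable.variable_gene_mask]
        labels = cluster_cells(separable.counts, features, resolution=0.1, seed=0)
        assert purity_score(labels, separable.group_labels == 0).purity == 1.0
        assert purity_score(labels, separable.group_labels == 1).purity == 1.0

    def test_too_few_features_rejected(self, separable):
        with pytest.raises(ValueError):
            cluster_cells(separable.counts, ["gene_0"], seed=0)
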