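"""Ward clustering, classical-MDS embedding, and BIC/WSS cluster-count
selection."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from persnet import (
    cut_dendrogram,
    embed_distances,
    select_k,
    ward_linkage,
)

from _oracles import random_dissimilarity


def two_pair_matrix():
    # two tight pairs {a,b} and {c,d}: within 0.1, between 1.0
    D = np.full((4, 4), 1.0)
    D[0, 1] = D[1, 0] = D[2, 3] = D[3, 2] = 0.1
    np.fill_diagonal(D, 0.0)
    return D


def blobs_distance_matrix(n_clusters=4, per_cluster=5, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((n_clusters, 3)) * sep
    points = np.vstack(
        [c + 0.1 * rng.standard_normal((per_cluster, 3)) for c in centers]
    )
    labels = np.repeat(np.arange(n_clusters), per_cluster)
    return squareform(pdist(points)), labels


class TestWardLinkage:
    def test_two_leaves_merge_at_their_distance(self):
        D = np.array([[0, 0.4], [0.4, 0]])
        tree = ward_linkage(D)
        assert tree.linkage.shape == (1, 4)
        assert tree.merge_heights[0] == pytest.approx(0.4)

    def test_two_pair_example_cut_recovers_pairs(self):
        tree = ward_linkage(two_pair_matrix())
        labels = cut_dendrogram(tree, 2)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_merge_heights_monotone_on_random_inputs(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            tree = ward_linkage(random_dissimilarity(rng, 9))
            assert np.all(np.diff(tree.merge_heights) >= -1e-12)

    def test_label_permutation_leaves_partition_unchanged(self):
        rng = np.random.default_rng(23)
        D = random_dissimilarity(rng, 8)
        perm = rng.permutation(8)
        base = cut_dendrogram(ward_linkage(D), 3)
        shuffled = cut_dendrogram(ward_linkage(D[np.ix_(perm, perm)]), 3)
        assert adjusted_rand_score(base[perm], shuffled) == pytest.approx(1.0)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ward_linkage(np.array([[0, 1.0], [0.5, 0]]))

    def test_newick_has_all_leaves(self):
        tree = ward_linkage(two_pair_matrix())
        newick = tree.to_newick()
        assert newick.endswith(";")
        for label in tree.labels:
            assert label in newick


class TestCutDendrogram:
    def test_k_one_and_k_n_are_trivial_partitions(self):
        rng = np.random.default_rng(29)
        D = random_dissimilarity(rng, 7)
        tree = ward_linkage(D)
        assert len(set(cut_dendrogram(tree, 1))) == 1
        assert len(set(cut_dendrogram(tree, 7))) == 7

    def test_cuts_are_nested_refinements(self):
        rng = np.random.default_rng(31)
        tree = ward_linkage(random_dissimilarity(rng, 10))
        for k in range(2, 10):
            coarse = cut_dendrogram(tree, k - 1)
            fine = cut_dendrogram(tree, k)
            # each fine cluster sits inside exactly one coarse cluster
            for c in np.unique(fine):
                assert len(np.unique(coarse[fine == c])) == 1

    def test_out_of_range_k_rejected(self):
        tree = ward_linkage(two_pair_matrix())
        for k in (0, 5):
            with pytest.raises(ValueError):
                cut_dendrogram(tree, k)


class TestEmbedDistances:
    def test_equilateral_triangle_recovered(self):
        D = np.ones((3, 3)) - np.eye(3)
        X = embed_distances(D)
        assert np.allclose(squareform(pdist(X)), D, atol=1e-9)

    def test_euclidean_distances_reproduced_exactly(self):
        rng = np.random.default_rng(37)
        points = rng.standard_normal((8, 3))
        D = squareform(pdist(points))
        X = embed_distances(D)
        assert np.allclose(squareform(pdist(X)), D, atol=1e-9)

    def test_dropped_eigenvalue_bookkeeping(self):
        # the Gram-matrix error of the embedding equals exactly the energy of
        # the discarded negative eigenvalues
        rng = np.random.default_rng(41)
        D = random_dissimilarity(rng, 10)  # generic, non-Euclidean
        n = 10
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        X = embed_distances(D)
        eigval = np.linalg.eigvalsh(B)
        expected_err = np.sqrt((eigval[eigval < 0] ** 2).sum())
        assert np.linalg.norm(X @ X.T - B) == pytest.approx(expected_err, rel=1e-6)

    def test_dims_validation(self):
        D = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            embed_distances(D, dims=0)
        with pytest.raises(ValueError):
            embed_distances(D, dims=3)


class TestSelectK:
    def test_bic_formula_consistency(self):
        # BIC(k) must equal n*ln(WSS_k/n) + k*ln(n) for the returned WSS
        D, _ = blobs_distance_matrix(seed=3)
        result = select_k(D, k_max=6, restarts=10, seed=1)
        n = D.shape[0]
        for k, wss, bic in zip(result.k_grid, result.wss_curve, result.bic_curve):
            assert bic == pytest.approx(n * np.log(wss / n) + k * np.log(n), rel=1e-9)

    def test_wss_nonincreasing(self):
        D, _ = blobs_distance_matrix(seed=5)
        result = select_k(D, k_max=10, restarts=10, seed=2)
        assert all(
            later <= earlier + 1e-9
            for earlier, later in zip(result.wss_curve, result.wss_curve[1:])
        )

    def test_well_separated_blobs_select_true_k(self):
        D, labels = blobs_distance_matrix(n_clusters=4, seed=7)
        result = select_k(D, k_max=10, restarts=10, seed=3)
        assert result.k_elbow == 4
        assert result.k_selected == 4
        tree = ward_linkage(D)
        assert adjusted_rand_score(labels, cut_dendrogram(tree, 4)) == 1.0

    def test_k_max_validation(self):
        D, _ = blobs_distance_matrix()
        with pytest.raises(ValueError):
            select_k(D, k_max=D.shape[0])
        with pytest.raises(ValueError):
            select_k(D, k_max=1)

    def test_selection_deterministic_given_seed(self):
        D, _ = blobs_distance_matrix(seed=11)
        a = select_k(D, k_max=8, restarts=5, seed=9)
        b = select_k(D, k_max=8, restarts=5, seed=9)
        assert a == b
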