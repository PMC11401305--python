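import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

import bubbletree as bt
from bubbletree import (
    BootstrapConfig,
    ValidationError,
    bootstrap_distances,
    branch_support,
    build_tree,
    exact_pair_distance,
    memory_estimate,
    memory_estimate_gb,
    rank_pair_distance,
)
from bubbletree.io_model import ClusterAssignment, Embedding
from bubbletree.synthetic import MixtureSpec, clade_sets, \
    make_gaussian_mixture, make_tree_mixture
from bubbletree.treebuild import BubbleTree, DistanceEnsemble


def embedding_from(points):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    return Embedding(cell_ids=[f"c{i}" for i in range(len(points))],
                     matrix=points)


def assign(labels):
    return ClusterAssignment(
        cell_ids=[f"c{i}" for i in range(len(labels))],
        labels=[str(x) for x in labels])


def ensemble_from_matrix(D, ids, B=1):
    D = np.asarray(D, dtype=float)
    return DistanceEnsemble(
        per_iteration=np.repeat(D[None], B, axis=0), mean=D.copy(),
        cluster_ids=list(ids), subsample_sizes=np.ones(len(ids), int),
        cluster_sizes=np.ones(len(ids), int), config=BootstrapConfig(B=B),
    )


class TestExactPairDistance:
    def test_singletons(self):
        assert exact_pair_distance([[0.0]], [[3.0]]) == 3.0

    def test_duplicate_points(self):
        assert exact_pair_distance([[0.0], [0.0]], [[3.0], [3.0]]) == 3.0

    def test_all_pairs_mean(self):
        # pairs (0,10),(0,14),(2,10),(2,14): mean(10,14,8,12) = 11
        assert exact_pair_distance([[0.0], [2.0]],
                                   [[10.0], [14.0]]) == pytest.approx(11.0)

    def test_manhattan(self):
        assert exact_pair_distance([[0.0, 0.0]], [[1.0, 2.0]],
                                   metric="manhattan") == 3.0


class TestMemoryEstimate:
    def test_single_cell(self):
        assert memory_estimate(1) == 8

    def test_thousand_cells(self):
        assert memory_estimate(1000) == 8_000_000

    def test_million_cells_in_binary_gb(self):
        assert memory_estimate_gb(10**6, 8) == 7450


class TestBootstrapDistances:
    def test_zero_variance_clusters_give_exact_distance(self):
        emb = embedding_from([[0.0]] * 4 + [[5.0]] * 3)
        ens = bootstrap_distances(emb, assign(["a"] * 4 + ["b"] * 3),
                                  BootstrapConfig(B=8, N_eff=2, seed=0))
        assert np.all(ens.per_iteration[:, 0, 1] == 5.0)
        assert ens.mean[0, 1] == 5.0

    def test_symmetry_and_zero_diagonal(self, blobs5):
        emb, labels = blobs5
        ens = bootstrap_distances(emb, assign(labels),
                                  BootstrapConfig(B=10, N_eff=30, seed=1))
        np.testing.assert_array_equal(ens.mean, ens.mean.T)
        assert np.all(np.diag(ens.mean) == 0)
        assert np.all(ens.per_iteration >= 0)

    def test_subsample_sizes_capped(self, blobs5):
        emb, labels = blobs5
        ens = bootstrap_distances(emb, assign(labels),
                                  BootstrapConfig(B=2, N_eff=30, seed=0))
        assert np.all(ens.subsample_sizes == 30)
        assert np.all(ens.cluster_sizes == 100)

    def test_identical_seed_identical_ensemble(self, blobs5):
        emb, labels = blobs5
        cfg = BootstrapConfig(B=5, N_eff=20, seed=11)
        e1 = bootstrap_distances(emb, assign(labels), cfg)
        e2 = bootstrap_distances(emb, assign(labels), cfg)
        assert np.array_equal(e1.per_iteration, e2.per_iteration)

    def test_estimator_unbiased_within_3se(self):
        # small clusters, many iterations: the bootstrap mean approaches
        # the exact all-pairs mean distance
        spec = MixtureSpec(sizes=[15, 20, 12],
                           means=[[0, 0], [6, 0], [0, 7]], sd=1.0, seed=9)
        emb, attrs = make_gaussian_mixture(spec)
        a = bt.from_assignments(emb, attrs.data["label"])
        cfg = BootstrapConfig(B=800, N_eff=10, seed=5)
        ens = bootstrap_distances(emb, a, cfg)
        members = a.members()
        for i in range(3):
            for j in range(i + 1, 3):
                X = emb.matrix[emb.index_of(members[ens.cluster_ids[i]])]
                Y = emb.matrix[emb.index_of(members[ens.cluster_ids[j]])]
                exact = exact_pair_distance(X, Y)
                se = ens.per_iteration[:, i, j].std(ddof=1) / np.sqrt(ens.B)
                assert abs(ens.mean[i, j] - exact) < 3 * se

    def test_exact_small_clusters_option(self):
        emb = embedding_from([[0.0], [2.0], [10.0], [14.0]])
        ens = bootstrap_distances(
            emb, assign(["a", "a", "b", "b"]),
            BootstrapConfig(B=3, N_eff=5, seed=0,
                            exact_small_clusters=True))
        assert np.all(ens.per_iteration[:, 0, 1] == 11.0)

    def test_single_cluster_rejected(self):
        emb = embedding_from([[0.0], [1.0]])
        with pytest.raises(ValidationError):
            bootstrap_distances(emb, assign(["a", "a"]),
                                BootstrapConfig(B=2))


class TestBuildTree:
    def test_hand_upgma_three_tips(self):
        D = [[0, 1, 4], [1, 0, 5], [4, 5, 0]]
        tree = build_tree(ensemble_from_matrix(D, ["A", "B", "C"]))
        clades = tree.clades()
        assert clades[0] == frozenset({"A", "B"})
        assert tree.linkage[0, 2] == pytest.approx(1.0)
        assert tree.linkage[1, 2] == pytest.approx(4.5)

    def test_two_tips_single_merge(self):
        tree = build_tree(ensemble_from_matrix([[0, 3.5], [3.5, 0]],
                                               ["0", "1"]))
        assert tree.k == 2
        assert tree.heights().tolist() == [3.5]

    def test_tied_distances_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        t1 = build_tree(ensemble_from_matrix(D, list("abcd")))
        t2 = build_tree(ensemble_from_matrix(D, list("abcd")))
        assert t1.clades() == t2.clades()
        assert t1.clades()[0] == frozenset({"a", "b"})

    def test_non_finite_distances_rejected(self):
        D = [[0, np.inf], [np.inf, 0]]
        with pytest.raises(ValidationError):
            build_tree(ensemble_from_matrix(D, ["a", "b"]))

    def test_heights_monotone_and_counts(self, blobs5):
        emb, labels = blobs5
        a = assign(labels)
        tree = bt.get_bubbletree(emb, a, BootstrapConfig(B=10, seed=0))
        h = tree.heights()
        assert np.all(np.diff(h) >= -1e-12)
        assert tree.n_total == emb.n

    def test_cophenetic_equals_input_for_ultrametric(self):
        # an exactly ultrametric distance matrix is reproduced by average
        # linkage cophenetic distances
        Z = hierarchy.linkage(np.array([1.0, 4.0, 4.0]), method="average")
        D = squareform(hierarchy.cophenet(Z))
        tree = build_tree(ensemble_from_matrix(D, list("abc")))
        np.testing.assert_allclose(tree.cophenetic().to_numpy(), D)


class TestBranchSupport:
    def star_trees(self, D, ids, B):
        return build_tree(ensemble_from_matrix(D, ids, B=B))

    def test_identical_bootstrap_full_support(self):
        D = [[0, 1, 4], [1, 0, 5], [4, 5, 0]]
        tree = self.star_trees(D, list("ABC"), B=10)
        branch_support(tree)
        assert np.all(tree.support == 10)

    def test_half_containing_clade(self):
        D1 = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], float)  # (A,B)
        D2 = np.array([[0, 5, 1], [5, 0, 4], [1, 4, 0]], float)  # (A,C)
        consensus = build_tree(ensemble_from_matrix(D1, list("ABC")))
        boots = [build_tree(ensemble_from_matrix(D, list("ABC")))
                 for D in [D1] * 5 + [D2] * 5]
        branch_support(consensus, bootstrap_trees=boots)
        by_clade = dict(zip(consensus.clades(), consensus.support))
        assert by_clade[frozenset("AB")] == 5
        assert by_clade[frozenset("ABC")] == 10

    def test_tip_set_mismatch_rejected(self):
        D = [[0, 1], [1, 0]]
        t1 = build_tree(ensemble_from_matrix(D, ["a", "b"]))
        t2 = build_tree(ensemble_from_matrix(D, ["a", "x"]))
        with pytest.raises(ValidationError):
            branch_support(t1, bootstrap_trees=[t2])

    def test_supports_bounded_by_b(self, blobs5):
        emb, labels = blobs5
        tree = bt.get_bubbletree(emb, assign(labels),
                                 BootstrapConfig(B=40, seed=2))
        assert np.all((0 <= tree.support) & (tree.support <= 40))

    def test_bipartition_mode_root_children_equal(self):
        # under unrooted matching the two clades meeting at the root are
        # the same bipartition, hence equal support
        emb, attrs, _ = make_tree_mixture((("A", "B"), ("C", "D")),
                                          [10.0, 2.0], sizes=15, sd=1.0,
                                          seed=4)
        a = bt.from_assignments(emb, attrs.data["label"])
        ens = bootstrap_distances(emb, a, BootstrapConfig(B=30, seed=1))
        tree = build_tree(ens)
        branch_support(tree, mode="bipartition")
        root_children = [c for c in tree.clades() if len(c) == 2]
        sup = dict(zip(tree.clades(), tree.support))
        assert sup[root_children[0]] == sup[root_children[1]]


class TestTreeRecovery:
    def test_recovered_for_separated_mixtures(self):
        # >= 8 sd separation between sibling means: the generative topology
        # should be recovered in at least 95% of seeded runs
        topo = (("A", "B"), ("C", "D"))
        expected = clade_sets(topo)
        hits = 0
        for seed in range(20):
            emb, attrs, _ = make_tree_mixture(topo, [24.0, 4.0], sizes=30,
                                              sd=1.0, seed=seed)
            a = bt.from_assignments(emb, attrs.data["label"])
            tree = bt.get_bubbletree(
                emb, a, BootstrapConfig(B=20, N_eff=30, seed=seed))
            got = {c for c in tree.clades() if 1 < len(c) < tree.k}
            hits += got == expected
        assert hits >= 19


class TestRankPairDistance:
    def test_two_profiles(self):
        out = rank_pair_distance({"a": [0.0], "b": [1.0]}, ("a", "b"))
        assert out == {"rank": 1, "n_pairs": 1, "distance": 1.0}

    def test_pair_count_for_69_profiles(self):
        rng = np.random.default_rng(0)
        profiles = {f"p{i}": rng.normal(size=5) for i in range(69)}
        out = rank_pair_distance(profiles, ("p0", "p1"))
        assert out["n_pairs"] == 2346

    def test_rank_on_a_line(self):
        out = rank_pair_distance({"a": [0.0], "b": [1.0], "c": [10.0]},
                                 ("a", "b"))
        assert out["rank"] == 1 and out["n_pairs"] == 3

    def test_ties_share_minimum_rank(self):
        out = rank_pair_distance(
            {"a": [0.0], "b": [2.0], "c": [4.0]}, ("b", "c"))
        assert out["rank"] == 1  # d(a,b) = d(b,c) = 2

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            rank_pair_distance({"a": [0.0], "b": [1.0, 2.0]}, ("a", "b"))
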