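"""Agglomeration engine: DPM merge priors, evidence recursion, greedy build, cut."""

import math

import numpy as np
import pytest

from gbhc.engine import (
    BHCConfig,
    DendroNode,
    build_tree,
    cut_tree,
    dpm_weights,
    make_leaf,
    node_evidence,
)
from gbhc.model import ClusterStats, NGHyperparams, stats_marginal_loglik

HP = NGHyperparams(1.0, 1.0, 1.0)


def fixed_hp(stats, left, right):
    return HP


def leaf(i, value=0.0):
    return make_leaf(i, ClusterStats.from_data(np.array([[value]])), 1.0, HP)


class TestDpmWeights:
    def test_two_leaves_alpha_one_gives_half(self):
        log_d, log_pi = dpm_weights(leaf(0), leaf(1), alpha=1.0)
        assert math.exp(log_pi) == pytest.approx(0.5, abs=1e-15)

    def test_small_alpha_forces_merging(self):
        # pi = alpha/(alpha + alpha^2) -> 1 as alpha -> 0+
        for alpha in [1e-3, 1e-6]:
            stats = ClusterStats.from_data(np.array([[0.0]]))
            a = make_leaf(0, stats, alpha, HP)
            b = make_leaf(1, stats, alpha, HP)
            _, log_pi = dpm_weights(a, b, alpha=alpha)
            assert math.exp(log_pi) == pytest.approx(1.0 / (1.0 + alpha),
                                                     rel=1e-12)

    def test_three_leaf_cascade_by_hand(self):
        # d_12 = Gamma(2) + 1 = 2; root pi = Gamma(3)/(Gamma(3) + 2*1) = 1/2
        l0, l1, l2 = leaf(0), leaf(1), leaf(2)
        log_d12, log_pi12 = dpm_weights(l0, l1, alpha=1.0)
        pair = DendroNode(members=np.array([0, 1]),
                          stats=l0.stats.merge(l1.stats),
                          log_d=log_d12, log_pi=log_pi12, left=l0, right=l1)
        assert math.exp(log_d12) == pytest.approx(2.0)
        _, log_pi = dpm_weights(pair, l2, alpha=1.0)
        assert math.exp(log_pi) == pytest.approx(0.5, rel=1e-14)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            dpm_weights(leaf(0), leaf(1), alpha=0.0)

    def test_merge_prior_is_a_probability(self, rng):
        node_a, node_b = leaf(0), leaf(1)
        for alpha in [0.01, 1.0, 100.0]:
            log_d, log_pi = dpm_weights(node_a, node_b, alpha)
            assert log_pi <= 0.0
            assert 0.0 < math.exp(log_pi) <= 1.0


class TestNodeEvidence:
    def test_symmetric_evidence_gives_half(self):
        a, b = leaf(0), leaf(1)
        h1 = a.log_ml_tree + b.log_ml_tree
        _, r = node_evidence(a, b, h1, math.log(0.5))
        assert r == pytest.approx(0.5, abs=1e-12)

    def test_three_to_one_odds(self):
        a, b = leaf(0), leaf(1)
        h1 = a.log_ml_tree + b.log_ml_tree + math.log(3.0)
        _, r = node_evidence(a, b, h1, math.log(0.5))
        assert r == pytest.approx(0.75, abs=1e-12)

    def test_matches_naive_arithmetic(self, rng):
        for _ in range(50):
            a, b = leaf(0), leaf(1)
            a.log_ml_tree = float(rng.uniform(-30, 0))
            b.log_ml_tree = float(rng.uniform(-30, 0))
            h1 = float(rng.uniform(-60, 0))
            pi = float(rng.uniform(0.05, 0.95))
            log_ml, r = node_evidence(a, b, h1, math.log(pi))
            naive = pi * math.exp(h1) + (1 - pi) * math.exp(
                a.log_ml_tree + b.log_ml_tree)
            assert log_ml == pytest.approx(math.log(naive), abs=1e-10)
            assert r == pytest.approx(pi * math.exp(h1) / naive, abs=1e-10)

    def test_unit_prior_forces_merge(self):
        a, b = leaf(0), leaf(1)
        log_ml, r = node_evidence(a, b, -3.0, 0.0)
        assert r == 1.0 and log_ml == -3.0

    def test_tree_ml_dominates_merge_term(self, rng):
        # logsumexp of two terms is at least either term
        for _ in range(20):
            a, b = leaf(0), leaf(1)
            h1 = float(rng.uniform(-50, 0))
            log_pi = float(rng.uniform(-5, -0.01))
            log_ml, _ = node_evidence(a, b, h1, log_pi)
            assert log_ml >= log_pi + h1 - 1e-12


class TestBuildTree:
    def test_single_observation(self):
        root = build_tree(np.array([[0.3]]), BHCConfig(), fixed_hp)
        assert root.is_leaf and root.r == 1.0

    def test_two_observations_single_merge(self):
        X = np.array([[0.1], [-0.2]])
        root = build_tree(X, BHCConfig(), fixed_hp)
        la = make_leaf(0, ClusterStats.from_data(X[:1]), 1.0, HP)
        lb = make_leaf(1, ClusterStats.from_data(X[1:]), 1.0, HP)
        _, log_pi = dpm_weights(la, lb, 1.0)
        h1 = stats_marginal_loglik(la.stats.merge(lb.stats), HP)
        log_ml, r = node_evidence(la, lb, h1, log_pi)
        assert root.r == pytest.approx(r, abs=1e-14)
        assert root.log_ml_tree == pytest.approx(log_ml, abs=1e-12)

    def test_two_point_root_matches_hand_recursion(self):
        # full closed-form trace of the two-point tree
        X = np.array([[0.5], [-0.25]])
        root = build_tree(X, BHCConfig(), fixed_hp)
        assert math.exp(root.log_pi) == pytest.approx(0.5, abs=1e-12)
        h1 = stats_marginal_loglik(ClusterStats.from_data(X), HP)
        split = (stats_marginal_loglik(ClusterStats.from_data(X[:1]), HP)
                 + stats_marginal_loglik(ClusterStats.from_data(X[1:]), HP))
        expected_ml = np.logaddexp(math.log(0.5) + h1,
                                   math.log(0.5) + split)
        assert root.log_ml_tree == pytest.approx(float(expected_ml),
                                                 abs=1e-12)
        assert root.r == pytest.approx(
            math.exp(math.log(0.5) + h1 - expected_ml), abs=1e-12)

    def test_greedy_merges_within_clusters_first(self, tiny_two_cluster_data):
        """On two tight, well-separated groups every within-group merger
        precedes any cross-group merger, matching exhaustive argmax."""
        root = build_tree(tiny_two_cluster_data, BHCConfig(), fixed_hp)
        left_group = {0, 1, 2}
        # the root's children partition the leaves into the two groups
        sides = [set(root.left.members.tolist()),
                 set(root.right.members.tolist())]
        assert left_group in sides

    def test_structure_is_deterministic(self, rng):
        X = rng.normal(size=(8, 2))
        r1 = build_tree(X, BHCConfig(), fixed_hp)
        r2 = build_tree(X, BHCConfig(), fixed_hp)
        assert [sorted(n.members.tolist()) for n in r1.nodes_postorder()] == \
               [sorted(n.members.tolist()) for n in r2.nodes_postorder()]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            build_tree(np.empty((0, 2)), BHCConfig(), fixed_hp)

    def test_eq3_dominance_everywhere(self, rng):
        X = rng.normal(size=(10, 2))
        root = build_tree(X, BHCConfig(), fixed_hp)
        for node in root.nodes_postorder():
            if not node.is_leaf:
                assert node.log_ml_tree >= node.log_pi + node.log_ml_h1 - 1e-12

    def test_members_partition_children(self, rng):
        X = rng.normal(size=(9, 2))
        root = build_tree(X, BHCConfig(), fixed_hp)
        for node in root.nodes_postorder():
            if not node.is_leaf:
                l = set(node.left.members.tolist())
                r = set(node.right.members.tolist())
                assert l.isdisjoint(r)
                assert l | r == set(node.members.tolist())


def _hand_tree(r_values):
    """Five-leaf tree with prescribed internal merge probabilities."""
    leaves = [leaf(i) for i in range(5)]

    def join(a, b, r):
        node = DendroNode(
            members=np.concatenate([a.members, b.members]),
            stats=a.stats.merge(b.stats), log_d=0.0, r=r, left=a, right=b)
        return node

    left = join(leaves[0], leaves[1], r_values["left"])
    rl = join(leaves[2], leaves[3], r_values["right.left"])
    right = join(rl, leaves[4], r_values["right"])
    return join(left, right, r_values["root"])


class TestCutTree:
    def test_all_high_r_one_cluster(self, rng):
        X = rng.normal(size=(4, 1)) * 0.01
        root = build_tree(X, BHCConfig(), fixed_hp)
        if all(n.r > 0.5 for n in root.nodes_postorder()):
            assert cut_tree(root).n_clusters() == 1

    def test_low_root_high_children_two_clusters(self):
        root = _hand_tree({"root": 0.3, "left": 0.9, "right": 0.8,
                           "right.left": 0.2})
        assert cut_tree(root, 0.5).n_clusters() == 2

    def test_hand_built_five_leaf_cut(self):
        # root splits (0.2), left survives (0.9), right splits (0.4),
        # right.left survives (0.8), leaf 4 is its own cluster: 3 clusters
        root = _hand_tree({"root": 0.2, "left": 0.9, "right": 0.4,
                           "right.left": 0.8})
        part = cut_tree(root, 0.5)
        assert part.n_clusters() == 3
        groups = {frozenset(v.tolist()) for v in part.clusters().values()}
        assert groups == {frozenset({0, 1}), frozenset({2, 3}),
                          frozenset({4})}

    def test_boundary_r_splits(self):
        root = _hand_tree({"root": 0.5, "left": 0.9, "right": 0.9,
                           "right.left": 0.9})
        assert cut_tree(root, 0.5).n_clusters() == 2

    def test_partition_covers_everything_once(self, rng):
        X = rng.normal(size=(12, 2))
        root = build_tree(X, BHCConfig(), fixed_hp)
        part = cut_tree(root)
        assert sorted(np.concatenate(
            [v for v in part.clusters().values()]).tolist()) == list(range(12))


class TestPartitionLevelInvariants:
    def test_label_invariance_under_row_permutation(self, tiny_two_cluster_data):
        from gbhc.evaluation import adjusted_rand_index
        X = np.vstack([tiny_two_cluster_data,
                       tiny_two_cluster_data[:2] + 0.01])
        part1 = cut_tree(build_tree(X, BHCConfig(), fixed_hp))
        perm = np.array([3, 0, 6, 1, 4, 7, 2, 5])
        part2 = cut_tree(build_tree(X[perm], BHCConfig(), fixed_hp))
        # same partition up to relabeling: ARI between aligned labelings is 1
        assert adjusted_rand_index(part1.labels[perm], part2.labels) == \
            pytest.approx(1.0)

    def test_cluster_count_monotone_in_alpha(self):
        rng = np.random.default_rng(5)
        centers = np.array([-4.0, 0.0, 4.0])
        X = (centers[rng.integers(0, 3, 30)] + 0.05 * rng.normal(size=30))
        X = ((X - X.mean()) / X.std(ddof=1))[:, None]
        counts = []
        for alpha in [0.01, 1.0, 100.0]:
            root = build_tree(X, BHCConfig(alpha=alpha), fixed_hp)
            counts.append(cut_tree(root).n_clusters())
        assert counts == sorted(counts)
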