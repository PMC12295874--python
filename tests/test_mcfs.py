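"""Unit and property tests for the MCFS-ID core: entropy/IG arithmetic,
tree induction against a brute-force oracle, the RI and ID-graph formulas on
hand-built forests, determinism, and permutation-cutoff behavior."""

import itertools

import numpy as np
import pandas as pd
import pytest

from epireg.mcfs import (FittedTree, IDGraph, MCFSParams, TreeNode,
                         build_tree, compute_id_graph, entropy,
                         idgraph_view, information_gain, permutation_cutoff,
                         predict_tree, ri_from_trees, run_mcfs,
                         run_mcfs_with_cutoff, tree_quality,
                         variance_reduction, weighted_accuracy)


class TestElementaryStats:
    @pytest.mark.parametrize("counts,expected", [
        ((10, 0), 0.0),
        ((5, 5), 1.0),
        ((3, 1), 0.8112781244591328),   # -sum p log2 p evaluated directly
        ((1, 1, 1, 1), 2.0),
    ])
    def test_entropy_values(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected, abs=1e-12)

    def test_entropy_rejects_empty(self):
        with pytest.raises(ValueError):
            entropy((0, 0))

    def test_information_gain_perfect_split(self):
        parent = [0] * 5 + [1] * 5
        assert information_gain(parent, [0] * 5, [1] * 5) == pytest.approx(1.0)

    def test_information_gain_uninformative_split(self):
        parent = [0, 0, 1, 1]
        assert information_gain(parent, [0, 1], [0, 1]) == pytest.approx(0.0)

    def test_variance_reduction_hand_case(self):
        # parent {0,0,4,4}: population variance 4; pure children -> VR = 4
        assert variance_reduction([0, 0, 4, 4], [[0, 0], [4, 4]]) == \
            pytest.approx(4.0)

    @pytest.mark.parametrize("y_true,y_pred,expected", [
        (["a"] * 4, ["a"] * 4, 1.0),
        (["a"] * 90 + ["b"] * 10, ["a"] * 100, 0.5),
        (["a"] * 10 + ["b"] * 10,
         ["a"] * 8 + ["b"] * 2 + ["b"] * 6 + ["a"] * 4, 0.7),
    ])
    def test_weighted_accuracy(self, y_true, y_pred, expected):
        assert weighted_accuracy(y_true, y_pred) == pytest.approx(expected)


def brute_force_best_split(X, y):
    """Exhaustive search over all (feature, threshold) splits, maximizing IG;
    independent oracle for the greedy tree root."""
    best = (-1.0, None, None)
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        for a, b in zip(vals, vals[1:]):
            thr = (a + b) / 2
            mask = X[:, j] <= thr
            ig = information_gain(y, y[mask], y[~mask])
            if ig > best[0] + 1e-12:
                best = (ig, j, thr)
    return best


class TestTree:
    def test_perfect_feature_gives_depth_one_tree(self):
        X = np.array([[0.], [0.], [0.], [1.], [1.], [1.]])
        y = np.array([0, 0, 0, 1, 1, 1])
        root = build_tree(X, y, ["f"])
        assert root.feature == "f"
        assert root.ig == pytest.approx(1.0)
        assert root.left.is_leaf and root.right.is_leaf

    def test_pure_target_gives_single_leaf(self):
        X = np.array([[0.], [1.], [2.]])
        root = build_tree(X, np.array([1, 1, 1]), ["f"])
        assert root.is_leaf and root.prediction == 1

    def test_constant_features_give_single_leaf(self):
        X = np.zeros((6, 3))
        y = np.array([0, 1, 0, 1, 0, 1])
        assert build_tree(X, y, ["a", "b", "c"]).is_leaf

    @pytest.mark.parametrize("seed", range(5))
    def test_root_split_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 2)).round(1)
        y = np.array([0, 0, 0, 1, 1, 1])
        root = build_tree(X, y, ["a", "b"])
        ig, j, thr = brute_force_best_split(X, y)
        if ig <= 1e-12:
            assert root.is_leaf
        else:
            assert root.ig == pytest.approx(ig, abs=1e-12)
            # ties may pick the other feature only at exactly equal gain
            own = brute_force_best_split(X[:, [{"a": 0, "b": 1}[root.feature]]], y)[0]
            assert own == pytest.approx(ig, abs=1e-12)

    def test_child_sample_counts_sum_to_parent(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        y = rng.integers(0, 2, size=40)
        root = build_tree(X, y, list("abcd"))
        stack = [root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                assert node.left.n + node.right.n == node.n
                assert node.ig >= 0
                stack.extend([node.left, node.right])

    def test_regression_tree_reduces_variance(self):
        X = np.array([[0.], [0.], [1.], [1.]])
        y = np.array([0., 0., 4., 4.])
        root = build_tree(X, y, ["f"], task="regression")
        assert root.ig == pytest.approx(4.0)
        pred = predict_tree(root, X, {"f": 0}).astype(float)
        assert np.allclose(pred, y)


class TestRIAndIDGraph:
    def _hand_forest(self):
        # tree 1: q=1.0, one node on g with IG 1.0 at the root (fraction 1.0)
        t1 = FittedTree(root=TreeNode(
            n=10, prediction=0, feature="g", threshold=0.0, ig=1.0,
            left=TreeNode(n=5, prediction=0), right=TreeNode(n=5, prediction=1)),
            quality=1.0)
        # tree 2: q=0.5, g in one node with IG 0.5 at sample fraction 0.5
        inner = TreeNode(n=5, prediction=0, feature="g", threshold=0.0, ig=0.5,
                         left=TreeNode(n=2, prediction=0),
                         right=TreeNode(n=3, prediction=1))
        t2 = FittedTree(root=TreeNode(
            n=10, prediction=0, feature="h", threshold=0.0, ig=0.3,
            left=inner, right=TreeNode(n=5, prediction=1)), quality=0.5)
        return t1, t2

    def test_ri_hand_arithmetic(self):
        t1, t2 = self._hand_forest()
        ri = ri_from_trees([t1, t2], u=1.0, v=1.0)
        # 1.0*1.0*1.0 + 0.5*0.5*0.5 = 1.125 by the documented formula
        assert ri["g"] == pytest.approx(1.125, abs=1e-12)

    def test_ri_additivity_over_tree_sets(self):
        t1, t2 = self._hand_forest()
        joint = ri_from_trees([t1, t2])
        sep1, sep2 = ri_from_trees([t1]), ri_from_trees([t2])
        for f in joint:
            assert joint[f] == pytest.approx(
                sep1.get(f, 0) + sep2.get(f, 0), abs=1e-12)

    def test_id_edge_hand_arithmetic(self):
        root = TreeNode(n=100, prediction=0, feature="f1", threshold=0.0,
                        ig=1.0,
                        left=TreeNode(n=40, prediction=0, feature="f2",
                                      threshold=0.0, ig=0.5,
                                      left=TreeNode(n=20, prediction=0),
                                      right=TreeNode(n=20, prediction=1)),
                        right=TreeNode(n=60, prediction=1))
        g = compute_id_graph([FittedTree(root=root, quality=1.0)])
        assert g.edges == {("f1", "f2"): pytest.approx(0.2)}

    def test_id_graph_empty_for_depth_one_forest(self):
        t1, _ = self._hand_forest()
        assert compute_id_graph([t1]).edges == {}

    def test_id_weights_double_with_duplicate_trees(self):
        _, t2 = self._hand_forest()
        one = compute_id_graph([t2])
        two = compute_id_graph([t2, t2])
        for e, w in one.edges.items():
            assert two.edges[e] == pytest.approx(2 * w)

    def test_idgraph_view_matches_brute_force(self):
        g = IDGraph()
        weights = {("a", "b"): 3.0, ("b", "c"): 5.0, ("c", "d"): 1.0,
                   ("a", "c"): 4.0, ("d", "e"): 2.0}
        for (p, c), w in weights.items():
            g.add(p, c, w)
        ranking = pd.DataFrame({"feature": list("abcde"),
                                "RI": [5, 4, 3, 2, 1]})
        view = idgraph_view(g, ranking, top_nodes=3, top_edges=2)
        assert view.edges == {("b", "c"): 5.0, ("a", "c"): 4.0}
        full = idgraph_view(g, ranking, top_nodes=10, top_edges=10)
        assert full.edges == g.edges


class TestRunMCFS:
    def _toy(self, n=60, p=12, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"f{i:02d}" for i in range(p)])
        y = pd.Series(rng.integers(0, 2, size=n).astype(str))
        y.index = X.index
        return X, y

    def test_planted_perfect_feature_ranks_first(self):
        X, y = self._toy(seed=1)
        X["f00"] = (y == "1").astype(float)
        params = MCFSParams(m=6, projections_per_feature=6, t=3, n_perm=5,
                            seed=2)
        res = run_mcfs(X, y, params)
        assert res.ranking.iloc[0]["feature"] == "f00"

    def test_same_seed_reproduces_ranking_cutoff_and_graph(self):
        X, y = self._toy(seed=2)
        params = MCFSParams(m=6, projections_per_feature=4, t=2, n_perm=3,
                            seed=5)
        a = run_mcfs_with_cutoff(X, y, params)
        b = run_mcfs_with_cutoff(X, y, params)
        pd.testing.assert_frame_equal(a.ranking, b.ranking)
        assert a.cutoff == b.cutoff
        assert a.id_graph.edges == b.id_graph.edges

    def test_scale_invariance_of_ranking_and_graph(self):
        X, y = self._toy(seed=3)
        params = MCFSParams(m=6, projections_per_feature=4, t=2, n_perm=1,
                            seed=5)
        a = run_mcfs(X, y, params)
        X2 = X.copy()
        X2["f03"] = X2["f03"] * 17.0   # positive rescale of one feature
        b = run_mcfs(X2, y, params)
        pd.testing.assert_frame_equal(a.ranking, b.ranking)
        assert set(a.id_graph.edges) == set(b.id_graph.edges)
        for e in a.id_graph.edges:
            assert a.id_graph.edges[e] == pytest.approx(b.id_graph.edges[e])

    def test_permutation_cutoff_singleton_equals_single_max(self):
        X, y = self._toy(seed=4)
        params = MCFSParams(m=6, projections_per_feature=3, t=2, n_perm=1,
                            seed=9)
        cutoff = permutation_cutoff(X, y, params)
        rng = np.random.default_rng(params.seed + 1)
        y_perm = rng.permutation(np.asarray(y))
        ref = run_mcfs(X, y_perm, params,
                       rng=np.random.default_rng(params.seed + 1))
        # the cutoff run consumed the rng for the permutation first
        rng2 = np.random.default_rng(params.seed + 1)
        y_perm2 = rng2.permutation(np.asarray(y))
        ref2 = run_mcfs(X, y_perm2, params, rng=rng2)
        assert cutoff == pytest.approx(float(ref2.ranking["RI"].max()))

    def test_null_features_mostly_below_cutoff(self):
        # pure-noise target: on average few features pass the cutoff
        fracs = []
        for seed in range(8):
            X, y = self._toy(n=50, p=20, seed=seed + 10)
            params = MCFSParams(m=8, projections_per_feature=3, t=2,
                                n_perm=10, seed=seed)
            res = run_mcfs_with_cutoff(X, y, params)
            fracs.append(res.ranking["significant"].mean())
        assert np.mean(fracs) <= 0.05

    def test_m_larger_than_feature_count_is_clamped(self):
        X, y = self._toy(n=30, p=4, seed=6)
        params = MCFSParams(m=50, projections_per_feature=2, t=2, n_perm=1,
                            seed=0)
        with pytest.warns(UserWarning, match="clamped"):
            res = run_mcfs(X, y, params)
        assert len(res.ranking) == 4

    def test_invalid_params_rejected(self):
        for kw in ({"m": 1}, {"u": -1}, {"n_perm": 0},
                   {"train_fraction": 1.0}):
            with pytest.raises(ValueError):
                MCFSParams(**kw)
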