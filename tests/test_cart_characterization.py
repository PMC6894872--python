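import numpy as np
import pytest

from mvextrap._errors import DataError
from mvextrap.cart_characterization import (
    TreeNode,
    fit_tree,
    predict_tree,
    render_tree,
    tree_summary,
)


def check_counts_recursive(node: TreeNode):
    if node.is_leaf:
        return
    assert node.counts[0] == node.left.counts[0] + node.right.counts[0]
    assert node.counts[1] == node.left.counts[1] + node.right.counts[1]
    assert np.isclose(node.node_fraction, node.left.node_fraction + node.right.node_fraction)
    check_counts_recursive(node.left)
    check_counts_recursive(node.right)


def training_accuracy(tree, X, y, names):
    hits = 0
    for row, label in zip(X, y):
        pred, _ = predict_tree(tree, dict(zip(names, row)))
        hits += (pred == "extrapolation") == bool(label)
    return hits / len(y)


class TestFitTree:
    def test_constant_index_yields_single_leaf(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        tree = fit_tree(X, np.zeros(20, dtype=int))
        assert tree.is_leaf
        assert tree.majority_label == "prediction"
        assert tree.counts == (20, 0)

    def test_perfect_separation_recovers_threshold_at_depth_one(self):
        rng = np.random.default_rng(1)
        x1 = np.concatenate([rng.uniform(0, 1, 30), rng.uniform(2, 3, 10)])
        x2 = rng.standard_normal(40)
        y = (x1 > 1.5).astype(int)
        tree = fit_tree(np.column_stack([x1, x2]), y, min_leaf=1)
        assert tree.split_variable == "x1"
        assert max(x1[x1 < 1.5]) < tree.split_threshold < min(x1[x1 > 1.5])
        assert tree.left.is_leaf and tree.right.is_leaf
        assert tree.left.counts == (30, 0)
        assert tree.right.counts == (0, 10)

    def test_hand_computed_gini_decrease_on_eight_rows(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        y = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        tree = fit_tree(x[:, None], y, min_leaf=1, max_depth=1)
        # parent gini = 1 - (3/8)^2 - (5/8)^2 = 30/64; best split x < 3.5:
        # left {0,0,0} pure, right {1,1,1,1,1} pure -> decrease = 8 * 30/64 = 3.75
        assert tree.split_threshold == 3.5
        parent_gini = 1 - (3 / 8) ** 2 - (5 / 8) ** 2
        assert np.isclose(tree.impurity_decrease, 8 * parent_gini)

    def test_child_counts_sum_to_parent(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 4))
        y = (X[:, 0] + 0.5 * X[:, 2] + rng.normal(0, 0.5, 200) > 1).astype(int)
        tree = fit_tree(X, y, max_depth=4, min_leaf=5)
        check_counts_recursive(tree)
        assert np.isclose(tree.node_fraction, 1.0)

    def test_purity_non_decreasing_with_depth(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((300, 3))
        y = ((X[:, 0] > 0.3) & (X[:, 1] < 0.5)).astype(int)
        names = ["x1", "x2", "x3"]
        accs = [
            training_accuracy(fit_tree(X, y, max_depth=d, min_leaf=1), X, y, names)
            for d in (1, 2, 3, 4)
        ]
        assert all(a2 >= a1 - 1e-12 for a1, a2 in zip(accs, accs[1:]))

    def test_tail_planted_extrapolations_identify_root_variable(self):
        # extrapolations live in one covariate's upper tail; across replicates
        # the root split should find that covariate far above chance
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((150, 5))
            y = (X[:, 2] > 1.6).astype(int)
            if y.sum() < 2:
                y[np.argsort(X[:, 2])[-3:]] = 1
            tree = fit_tree(X, y, min_leaf=2)
            hits += tree.split_variable == "x3"
        assert hits >= 8

    def test_missing_covariates_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 1.0]])
        with pytest.raises(DataError):
            fit_tree(X, [0, 1])

    def test_non_binary_index_rejected(self):
        with pytest.raises(DataError):
            fit_tree(np.ones((3, 1)), [0, 1, 2])

    def test_balanced_class_weight_can_flip_majority(self):
        # 90/10 imbalance: the rare class dominates once inverse weighted
        x = np.concatenate([np.zeros(9), np.ones(1)])
        y = np.concatenate([np.zeros(9, int), np.ones(1, int)])
        unweighted = fit_tree(x[:, None], y, max_depth=0)
        weighted = fit_tree(x[:, None], y, max_depth=0, class_weight={0: 1.0, 1: 20.0})
        assert unweighted.majority_label == "prediction"
        assert weighted.majority_label == "extrapolation"

    def test_matches_sklearn_on_clean_split_data(self):
        sklearn = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(7)
        X = rng.standard_normal((120, 3))
        y = (1.5 * X[:, 1] - X[:, 0] + rng.normal(0, 0.3, 120) > 0.5).astype(int)
        ours = fit_tree(X, y, max_depth=3, min_leaf=5)
        ref = sklearn.DecisionTreeClassifier(
            max_depth=3, min_samples_leaf=5, random_state=0
        ).fit(X, y)
        # same impurity criterion: root split variable and threshold agree
        assert f"x{ref.tree_.feature[0] + 1}" == ours.split_variable
        assert np.isclose(ref.tree_.threshold[0], ours.split_threshold, atol=1e-8)
        acc_ours = training_accuracy(ours, X, y, ["x1", "x2", "x3"])
        acc_ref = ref.score(X, y)
        assert abs(acc_ours - acc_ref) < 0.05


class TestPredictTree:
    def test_single_leaf_always_returns_leaf_label(self):
        tree = fit_tree(np.zeros((5, 1)), np.ones(5, dtype=int))
        label, path = predict_tree(tree, {"x1": 123.0})
        assert label == "extrapolation"
        assert path == []

    def test_value_at_threshold_routes_right(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0, 0, 1, 1])
        tree = fit_tree(x[:, None], y, min_leaf=1)
        assert tree.split_threshold == 1.5
        label, path = predict_tree(tree, {"x1": 1.5})
        assert label == "extrapolation"
        assert path == ["x1 >= 1.5"]

    def test_training_rows_reproduce_leaf_counts(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 2))
        y = (X[:, 0] > 0).astype(int)
        tree = fit_tree(X, y, max_depth=2, min_leaf=5)
        counts = {}
        for row, label in zip(X, y):
            _, path = predict_tree(tree, {"x1": row[0], "x2": row[1]})
            counts.setdefault(tuple(path), [0, 0])
            counts[tuple(path)][label] += 1

        def leaves(node, path):
            if node.is_leaf:
                yield tuple(path), node.counts
                return
            yield from leaves(node.left, path + [f"{node.split_variable} < {node.split_threshold:g}"])
            yield from leaves(node.right, path + [f"{node.split_variable} >= {node.split_threshold:g}"])

        for path, (n0, n1) in leaves(tree, []):
            assert counts[path] == [n0, n1]

    def test_missing_split_variable_rejected(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        tree = fit_tree(x[:, None], np.array([0, 0, 1, 1]), min_leaf=1)
        with pytest.raises(DataError):
            predict_tree(tree, {"other": 1.0})


class TestSummaryAndRendering:
    def test_depth_one_importance_is_its_decrease(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        tree = fit_tree(x[:, None], np.array([0, 0, 1, 1]), min_leaf=1)
        ranking = tree_summary(tree)
        assert ranking == [("x1", tree.impurity_decrease)]

    def test_leaf_only_tree_empty_ranking(self):
        tree = fit_tree(np.zeros((5, 1)), np.zeros(5, dtype=int))
        assert tree_summary(tree) == []

    def test_two_variable_ranking_matches_construction(self):
        # x1 gives the dominant split, x2 refines: importance(x1) > importance(x2)
        rng = np.random.default_rng(8)
        x1 = np.concatenate([rng.uniform(0, 1, 50), rng.uniform(3, 4, 50)])
        x2 = rng.standard_normal(100)
        y = ((x1 > 2) | ((x1 < 2) & (x2 > 1.2))).astype(int)
        tree = fit_tree(np.column_stack([x1, x2]), y, max_depth=2, min_leaf=2)
        ranking = dict(tree_summary(tree))
        assert tree.split_variable == "x1"
        if "x2" in ranking:
            assert ranking["x1"] > ranking["x2"]

    def test_render_contains_counts_and_thresholds(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        tree = fit_tree(x[:, None], np.array([0, 0, 1, 1]), min_leaf=1)
        text = render_tree(tree)
        assert "x1 < 1.5" in text
        assert "records=100.0%" in text
        assert "<leaf>" in text
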