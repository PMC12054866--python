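"""Ordinal trees and bagged forests: split oracle, pruning, bagging contract."""

import numpy as np
import pytest

from ordval.preprocess import DesignMatrix
from ordval.tree import COST_ABS, ForestFit, fit_forest, fit_tree


def plain_dm(X, names=None):
    names = names or [f"x{i}" for i in range(X.shape[1])]
    return DesignMatrix(
        X=X,
        columns=list(names),
        blocks={c: [i] for i, c in enumerate(names)},
        block_parents={},
        main_blocks=list(names),
        interaction_blocks=[],
        set_id=1,
    )


def brute_force_first_split(X, y):
    """Exhaustive oracle: the (col, thr) minimizing total |rank error| with
    each side labelled by its cost-minimizing category; None if no split
    strictly beats the unsplit cost. Ties: lowest column, lowest threshold."""

    def side_cost(rows):
        counts = np.bincount(y[rows], minlength=4)[1:]
        return min((COST_ABS[g] @ counts) for g in range(3))

    parent = side_cost(np.arange(len(y)))
    best = None
    for col in range(X.shape[1]):
        for thr in np.unique(X[:, col])[:-1]:
            left = np.flatnonzero(X[:, col] <= thr)
            right = np.flatnonzero(X[:, col] > thr)
            cost = side_cost(left) + side_cost(right)
            if best is None or cost < best[0] - 1e-12:
                best = (cost, col, thr)
    if best is None or best[0] >= parent - 1e-12:
        return None
    return best[1], best[2]


class TestTree:
    def test_perfectly_separable_single_split(self):
        X = np.linspace(0, 1, 30)[:, None]
        y = np.where(X[:, 0] < 0.5, 1, 3)
        tree = fit_tree(plain_dm(X), y, cp=0.0, minsplit=2)
        assert tree.depth() == 1
        assert np.all(tree.predict_category(X) == y)

    def test_huge_cp_prunes_to_root_modal(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3))
        y = rng.choice([1, 2, 3], size=100, p=[0.2, 0.6, 0.2])
        tree = fit_tree(plain_dm(X), y, cp=10.0, minsplit=2)
        assert tree.n_leaves() == 1
        assert np.all(tree.predict_category(X) == 2)

    def test_minsplit_exceeding_n_gives_root_only(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 2))
        y = rng.integers(1, 4, 20)
        tree = fit_tree(plain_dm(X), y, cp=0.0, minsplit=50)
        assert tree.n_leaves() == 1

    def test_invalid_parameters_error(self):
        X = np.zeros((10, 1))
        y = np.ones(10, dtype=int)
        with pytest.raises(ValueError):
            fit_tree(plain_dm(X), y, cp=-0.1)
        with pytest.raises(ValueError):
            fit_tree(plain_dm(X), y, minsplit=1)

    @pytest.mark.parametrize("seed", range(30))
    def test_first_split_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        X = np.round(rng.normal(size=(n, 2)), 2)
        y = rng.integers(1, 4, n)
        if len(np.unique(y)) < 2:
            y[0] = 1 + (y[0] % 3)
        oracle = brute_force_first_split(X, y)
        tree = fit_tree(plain_dm(X), y, cp=0.0, minsplit=2, criterion="cost")
        if oracle is None:
            assert tree.root.is_leaf
        else:
            col, thr = oracle
            assert tree.root.col == col
            assert thr < tree.root.thr < np.min(X[X[:, col] > thr, col])

    def test_leaf_probabilities_are_class_proportions(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3))
        y = rng.integers(1, 4, 200)
        tree = fit_tree(plain_dm(X), y, cp=0.0, minsplit=50)
        probs = tree.predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        leaves_total = sum(
            int(n.counts.sum()) for n in _collect_leaves(tree.root)
        )
        assert leaves_total == 200


def _collect_leaves(node):
    if node.is_leaf:
        return [node]
    return _collect_leaves(node.left) + _collect_leaves(node.right)


class TestForest:
    def test_degenerate_forest_equals_single_tree(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(150, 4))
        y = rng.choice([1, 2, 3], size=150, p=[0.3, 0.4, 0.3])
        dm = plain_dm(X)
        forest = fit_forest(dm, y, mtry=4, ntree=1, minsplit=20,
                            criterion="cost", bootstrap=False, seed=9)
        tree = fit_tree(dm, y, cp=0.0, minsplit=20, criterion="cost")
        Xt = rng.normal(size=(60, 4))
        np.testing.assert_allclose(forest.predict_proba(Xt), tree.predict_proba(Xt))

    def test_probability_contract_and_inbag_records(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 3))
        y = rng.integers(1, 4, 120)
        forest = fit_forest(plain_dm(X), y, mtry=2, ntree=20, seed=0)
        probs = forest.predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(probs >= 0)
        assert len(forest.inbag) == 20
        assert all(len(b) == 120 for b in forest.inbag)

    def test_oob_fraction_near_368(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 3))
        y = rng.integers(1, 4, 200)
        forest = fit_forest(plain_dm(X), y, mtry=2, ntree=60, seed=1)
        oob_fracs = [
            1.0 - len(np.unique(bag)) / 200 for bag in forest.inbag
        ]
        assert abs(np.mean(oob_fracs) - 0.368) < 0.02

    def test_mtry_out_of_range_errors(self):
        X = np.zeros((10, 2))
        y = np.tile([1, 2, 3], 4)[:10]
        with pytest.raises(ValueError):
            fit_forest(plain_dm(X), y, mtry=0, ntree=2)
        with pytest.raises(ValueError):
            fit_forest(plain_dm(X), y, mtry=5, ntree=2)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 3))
        y = rng.integers(1, 4, 80)
        dm = plain_dm(X)
        a = fit_forest(dm, y, mtry=2, ntree=10, seed=3).predict_proba(X)
        b = fit_forest(dm, y, mtry=2, ntree=10, seed=3).predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_deep_trees_on_null_data_overfit_in_bag(self):
        # bagged deep trees memorize duplicates: in-bag accuracy far above
        # chance even with outcome independent of all predictors
        rng = np.random.default_rng(8)
        X = rng.normal(size=(150, 4))
        y = rng.integers(1, 4, 150)
        forest = fit_forest(plain_dm(X), y, mtry=2, ntree=30, minsplit=2, seed=2)
        assert np.mean(forest.trees[0].depth() > 5) == 1.0
        fit_acc = np.mean(
            np.argmax(forest.predict_proba(X), axis=1) + 1 == y
        )
        oob_probs, covered = forest.oob_proba(plain_dm(X))
        oob_acc = np.mean(np.argmax(oob_probs[covered], axis=1) + 1 == y[covered])
        assert fit_acc > oob_acc + 0.15

    def test_json_round_trip_reproduces_predictions(self):
        import json

        rng = np.random.default_rng(9)
        X = rng.normal(size=(100, 3))
        y = rng.integers(1, 4, 100)
        dm = plain_dm(X)
        tree = fit_tree(dm, y, cp=0.01, minsplit=10)
        tree_back = type(tree).from_jsonable(json.loads(json.dumps(tree.to_jsonable())))
        np.testing.assert_array_equal(tree_back.predict_proba(X), tree.predict_proba(X))
        forest = fit_forest(dm, y, mtry=2, ntree=5, seed=0)
        forest_back = ForestFit.from_jsonable(
            json.loads(json.dumps(forest.to_jsonable()))
        )
        np.testing.assert_array_equal(
            forest_back.predict_proba(X), forest.predict_proba(X)
        )
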