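"""Gini trees and bagging: split oracle equivalence, determinism,
serialization, and an independent scikit-learn cross-check."""

import itertools

import numpy as np
import pytest

from epibeat.trees import (TreeEnsemble, _best_split_column,
                           _best_split_column_numpy, ensemble_from_json,
                           ensemble_to_json, find_best_split,
                           fit_bagged_ensemble, gini_impurity, grow_tree,
                           predict_ensemble, predict_matrix, predict_tree)


def brute_force_best_split(values, y, n_classes):
    """Exhaustive threshold enumeration with exact Gini gain."""
    values = np.asarray(values, float)
    y = np.asarray(y, int)
    n = len(values)

    def impurity(labels):
        if len(labels) == 0:
            return 0.0
        p = np.bincount(labels, minlength=n_classes) / len(labels)
        return 1.0 - np.sum(p * p)

    parent = impurity(y)
    uniq = np.unique(values)
    best = (None, 0.0)
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        thr = 0.5 * (lo + hi)
        if thr >= hi:
            thr = lo
        left = y[values <= thr]
        right = y[values > thr]
        gain = parent - (len(left) / n) * impurity(left) \
            - (len(right) / n) * impurity(right)
        if gain > best[1] + 1e-12:
            best = (float(thr), float(gain))
    return best


class TestGini:
    @pytest.mark.parametrize("counts,expected", [
        ([10, 0], 0.0),
        ([5, 5], 0.5),
        ([1, 1, 1, 1], 0.75),
        ([3, 1], 1 - (0.75**2 + 0.25**2)),
    ])
    def test_values(self, counts, expected):
        assert gini_impurity(np.array(counts)) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity(np.array([0, 0]))

    def test_bounds(self, rng):
        for _ in range(50):
            m = int(rng.integers(2, 6))
            c = rng.integers(0, 20, m)
            if c.sum() == 0:
                continue
            imp = gini_impurity(c)
            assert 0.0 <= imp <= 1.0 - 1.0 / m + 1e-12


class TestFindBestSplit:
    def test_perfect_separation_gain_equals_parent_impurity(self):
        thr, gain = find_best_split(np.array([1., 2., 3., 10., 11., 12.]),
                                    np.array([0, 0, 0, 1, 1, 1]))
        assert gain == pytest.approx(0.5)
        assert 3.0 < thr < 10.0

    def test_constant_feature(self):
        thr, gain = find_best_split(np.array([2.0] * 5),
                                    np.array([0, 1, 0, 1, 0]))
        assert thr is None and gain == 0.0

    def test_rows_api(self):
        rows = [(1.0, 0), (2.0, 0), (5.0, 1), (6.0, 1)]
        thr, gain = find_best_split(rows)
        assert gain == pytest.approx(0.5)
        assert thr == pytest.approx(3.5)

    def test_matches_brute_force_on_enumerated_tables(self, rng):
        """Oracle equivalence over all small tables (<=8 rows, values on
        a 4-point grid, <=3 classes), sampled exhaustively by seed."""
        grid = np.array([0.0, 0.5, 1.0, 1.5])
        for n in range(2, 9):
            for _ in range(60):
                values = grid[rng.integers(0, len(grid), n)]
                y = rng.integers(0, 3, n)
                m = int(y.max()) + 1
                thr_o, gain_o = brute_force_best_split(values, y, m)
                thr, gain = find_best_split(values, y, n_classes=m)
                assert gain == pytest.approx(gain_o, abs=1e-9)
                if gain_o > 0:
                    assert thr == pytest.approx(thr_o, abs=1e-12)

    def test_numba_and_numpy_paths_agree(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 40))
            values = np.round(rng.normal(0, 1, n), 2)
            y = rng.integers(0, 4, n)
            a = _best_split_column(values, y, 4)
            b = _best_split_column_numpy(values, y, 4)
            assert (a[0] is None) == (b[0] is None)
            assert a[1] == pytest.approx(b[1], abs=1e-12)
            if a[0] is not None:
                assert a[0] == pytest.approx(b[0], abs=1e-12)


class TestGrowTree:
    def test_pure_input_single_leaf(self):
        node = grow_tree(np.array([[1.], [2.], [3.]]),
                         np.array([1, 1, 1]), max_splits=5, n_classes=2)
        assert node.is_leaf and node.leaf_class == 1

    def test_single_split_is_global_best_stump(self, rng):
        X = rng.normal(0, 1, (40, 2))
        y = (X[:, 1] > 0.3).astype(int)
        stump = grow_tree(X, y, max_splits=1, n_classes=2)
        thr, gain = find_best_split(X[:, 1], y, n_classes=2)
        assert stump.split_feature == 1
        assert stump.split_threshold == pytest.approx(thr)

    def test_monotone_mapping_reaches_perfect_training_accuracy(self):
        x = np.linspace(0, 1, 60)
        y = (x * 4).astype(int).clip(0, 3)
        tree = grow_tree(x[:, None], y, max_splits=8, n_classes=4)
        pred = predict_tree(tree, x[:, None])
        assert np.mean(pred == y) == 1.0

    def test_split_budget_respected(self):
        x = np.arange(64, dtype=float)
        y = (np.arange(64) % 2).astype(int)
        tree = grow_tree(x[:, None], y, max_splits=3, n_classes=2)

        def count_splits(node):
            if node.is_leaf:
                return 0
            return 1 + count_splits(node.left) + count_splits(node.right)

        assert count_splits(tree) <= 3


class TestBagging:
    def make_task(self, rng, n=120):
        X = rng.normal(0, 1, (n, 2))
        y = ((X[:, 0] + 0.5 * rng.normal(0, 1, n)) > 0).astype(int)
        return X, y

    def test_single_tree_no_bootstrap_reduces_to_grow_tree(self, rng):
        X, y = self.make_task(rng)
        ens = fit_bagged_ensemble(X, y, ("f0", "f1"), n_trees=1,
                                  max_splits=6, seed=0, bootstrap=False)
        direct = grow_tree(X, y, max_splits=6, n_classes=2)
        np.testing.assert_array_equal(predict_matrix(ens, X),
                                      predict_tree(direct, X))

    def test_seed_determinism(self, rng):
        X, y = self.make_task(rng)
        a = fit_bagged_ensemble(X, y, ("f0", "f1"), n_trees=7, seed=5)
        b = fit_bagged_ensemble(X, y, ("f0", "f1"), n_trees=7, seed=5)
        assert ensemble_to_json(a) == ensemble_to_json(b)

    def test_bagging_reduces_holdout_variance(self):
        """Across seeds, the bagged ensemble's holdout accuracy varies
        less than a bootstrap-trained single tree's."""
        rng = np.random.default_rng(77)
        Xtr, ytr = self.make_task(rng, n=150)
        Xte, yte = self.make_task(rng, n=300)
        single, bagged = [], []
        for seed in range(12):
            e1 = fit_bagged_ensemble(Xtr, ytr, ("a", "b"), n_trees=1,
                                     max_splits=8, seed=seed)
            e25 = fit_bagged_ensemble(Xtr, ytr, ("a", "b"), n_trees=25,
                                      max_splits=8, seed=seed)
            single.append(np.mean(predict_matrix(e1, Xte) == yte))
            bagged.append(np.mean(predict_matrix(e25, Xte) == yte))
        assert np.var(bagged) < np.var(single)

    def test_vote_majority_and_ties(self):
        leaf0 = grow_tree(np.zeros((3, 1)), np.array([0, 0, 0]), 0, 2)
        leaf1 = grow_tree(np.zeros((3, 1)), np.array([1, 1, 1]), 0, 2)
        ens = TreeEnsemble([leaf0, leaf0, leaf1], ("x",), 2, 0, 0)
        assert predict_ensemble(ens, {"x": 0.0}) == 0
        tie = TreeEnsemble([leaf0, leaf1], ("x",), 2, 0, 0)
        assert predict_ensemble(tie, {"x": 0.0}) == 0  # tie -> lower class

    def test_missing_feature_named_in_error(self, rng):
        X, y = self.make_task(rng)
        ens = fit_bagged_ensemble(X, y, ("A1", "C2"), n_trees=3, seed=1)
        with pytest.raises(KeyError, match="C2"):
            predict_ensemble(ens, {"A1": 0.1})

    def test_json_round_trip_bit_exact(self, rng):
        X, y = self.make_task(rng)
        ens = fit_bagged_ensemble(X, y, ("f0", "f1"), n_trees=5, seed=3,
                                  scheme_name="lvpmax_20mmhg")
        text = ensemble_to_json(ens)
        again = ensemble_to_json(ensemble_from_json(text))
        assert text == again
        np.testing.assert_array_equal(
            predict_matrix(ensemble_from_json(text), X),
            predict_matrix(ens, X))

    def test_gain_nonnegative_on_random_tables(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 30))
            values = rng.normal(0, 1, n)
            y = rng.integers(0, 3, n)
            _, gain = find_best_split(values, y, n_classes=3)
            assert gain >= 0.0

    def test_feature_subset_cap(self):
        with pytest.raises(ValueError):
            TreeEnsemble([grow_tree(np.zeros((2, 1)),
                                    np.array([0, 1]), 0, 2)],
                         ("a", "b", "c", "d"), 2, 0, 0)


class TestSklearnCrossCheck:
    """scikit-learn is the independent oracle, never the implementation."""

    def test_stump_matches_sklearn_threshold(self, rng):
        sklearn = pytest.importorskip("sklearn.tree")
        X = rng.normal(0, 1, (200, 1))
        y = (X[:, 0] > 0.37).astype(int)
        stump = grow_tree(X, y, max_splits=1, n_classes=2)
        ref = sklearn.DecisionTreeClassifier(max_depth=1,
                                             criterion="gini").fit(X, y)
        assert stump.split_threshold == pytest.approx(
            ref.tree_.threshold[0], abs=1e-7)

    def test_training_accuracy_parity_on_noisy_task(self, rng):
        sklearn = pytest.importorskip("sklearn.tree")
        X = rng.normal(0, 1, (300, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        mine = grow_tree(X, y, max_splits=3, n_classes=2)
        ref = sklearn.DecisionTreeClassifier(
            max_leaf_nodes=4, criterion="gini").fit(X, y)
        acc_mine = np.mean(predict_tree(mine, X) == y)
        acc_ref = ref.score(X, y)
        assert acc_mine == pytest.approx(acc_ref, abs=0.02)
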