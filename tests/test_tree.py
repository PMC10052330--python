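"""C4.5 induction: entropy, gain-ratio splits, and threshold routing."""

import numpy as np
import pytest
from scipy.stats import entropy as scipy_entropy

from asvrf import TreeConfig, best_split, build_tree, entropy, tree_predict_proba
from asvrf.tree import TreeNode


def brute_force_splits(x, y, features, cfg, n_classes):
    """Independent oracle: every admissible (feature, midpoint, gain_ratio)."""
    n = len(y)

    def H(labels):
        return scipy_entropy(np.bincount(labels, minlength=n_classes), base=2)

    parent = H(y)
    out = []
    for f in features:
        values = np.unique(x[:, f])
        for lo, hi in zip(values[:-1], values[1:]):
            thr = (lo + hi) / 2.0
            left = y[x[:, f] <= thr]
            right = y[x[:, f] > thr]
            if min(len(left), len(right)) < cfg.min_samples_leaf:
                continue
            gain = parent - (len(left) * H(left) + len(right) * H(right)) / n
            p = len(left) / n
            split_h = scipy_entropy([p, 1 - p], base=2)
            if gain <= 1e-12 or split_h == 0:
                continue
            gr = gain / split_h
            if gr >= cfg.min_gain_ratio:
                out.append((f, thr, gr))
    return out


def test_entropy_values():
    assert entropy(np.array([1, 1, 1])) == 0.0
    assert entropy(np.array([0, 1, 0, 1])) == pytest.approx(1.0)
    assert entropy(np.array([0, 0, 0, 1])) == pytest.approx(0.8112781244591328, abs=1e-12)
    with pytest.raises(ValueError):
        entropy(np.array([]))


def test_best_split_four_points():
    """Values (.1,.2,.8,.9) / labels (A,A,B,B): split at 0.5, gain ratio 1."""
    x = np.array([[0.1], [0.2], [0.8], [0.9]])
    y = np.array([0, 0, 1, 1])
    f, thr, gr = best_split(x, y, np.array([0]), TreeConfig(), 2)
    assert f == 0
    assert thr == pytest.approx(0.5)
    assert gr == pytest.approx(1.0)


def test_best_split_pure_labels_none():
    x = np.array([[0.1], [0.5], [0.9]])
    assert best_split(x, np.array([1, 1, 1]), np.array([0]), TreeConfig(), 2) is None


def test_best_split_ignores_constant_feature():
    x = np.column_stack([np.full(4, 2.0), [0.1, 0.2, 0.8, 0.9]])
    y = np.array([0, 0, 1, 1])
    f, thr, _ = best_split(x, y, np.array([0, 1]), TreeConfig(), 2)
    assert f == 1


def test_best_split_matches_brute_force(rng):
    """Exhaustive agreement with an independent oracle on small datasets."""
    cfg = TreeConfig()
    for _ in range(200):
        n = int(rng.integers(2, 13))
        d = int(rng.integers(1, 4))
        x = np.round(rng.random((n, d)), 2)
        y = rng.integers(0, int(rng.integers(2, 4)), n)
        n_classes = int(y.max()) + 1 if y.size else 2
        got = best_split(x, y, np.arange(d), cfg, max(n_classes, 2))
        candidates = brute_force_splits(x, y, np.arange(d), cfg, max(n_classes, 2))
        if not candidates:
            assert got is None
            continue
        assert got is not None
        max_gr = max(c[2] for c in candidates)
        assert got[2] == pytest.approx(max_gr, abs=1e-9)
        ties = [c for c in candidates if c[2] >= max_gr - 1e-9]
        if len(ties) == 1:
            # unique optimum: exact same split is returned
            assert got[0] == ties[0][0]
            assert got[1] == pytest.approx(ties[0][1], abs=1e-12)
        else:
            # tied optimum: the returned split is one of the maximizers
            assert any(got[0] == f and abs(got[1] - t) < 1e-12 for f, t, _ in ties)


def test_build_tree_pure_input_single_leaf():
    tree = build_tree(np.ones((3, 1)), np.zeros(3, dtype=int), np.array([0]), TreeConfig(), 2)
    assert tree.is_leaf
    np.testing.assert_allclose(tree.proba, [(3 + 1) / 5, 1 / 5])


def test_build_tree_four_points_depth_one():
    x = np.array([[0.1], [0.2], [0.8], [0.9]])
    y = np.array([0, 0, 1, 1])
    tree = build_tree(x, y, np.array([0]), TreeConfig(), 2)
    assert not tree.is_leaf
    assert tree.depth() == 1
    assert tree.left.is_leaf and tree.right.is_leaf
    # Laplace-smoothed pure leaves of 2 rows: (2+1)/(2+2)
    np.testing.assert_allclose(tree.left.proba, [0.75, 0.25])
    np.testing.assert_allclose(tree.right.proba, [0.25, 0.75])


def test_build_tree_memorizes_consistent_data(rng):
    """Unlimited depth, min_samples_leaf=1: 100% training accuracy."""
    x = rng.random((40, 3))
    y = rng.integers(0, 2, 40)
    tree = build_tree(x, y, np.arange(3), TreeConfig(), 2)
    pred = np.argmax(tree_predict_proba(tree, x), axis=1)
    np.testing.assert_array_equal(pred, y)


def test_build_tree_respects_max_depth(rng):
    x = rng.random((60, 2))
    y = rng.integers(0, 2, 60)
    tree = build_tree(x, y, np.arange(2), TreeConfig(max_depth=3), 2)
    assert tree.depth() <= 3


def test_build_tree_terminates_on_inseparable_data():
    # duplicated x with conflicting labels cannot be split at all
    x = np.array([[0.5], [0.5], [0.5], [0.5]])
    y = np.array([0, 1, 0, 1])
    tree = build_tree(x, y, np.array([0]), TreeConfig(), 2)
    assert tree.is_leaf
    np.testing.assert_allclose(tree.proba, [0.5, 0.5])


def test_build_tree_deterministic(rng):
    x = rng.random((50, 3))
    y = rng.integers(0, 3, 50)
    t1 = build_tree(x, y, np.arange(3), TreeConfig(), 3)
    t2 = build_tree(x, y, np.arange(3), TreeConfig(), 3)
    assert t1.to_dict() == t2.to_dict()


def test_build_tree_empty_input():
    with pytest.raises(ValueError, match="empty"):
        build_tree(np.empty((0, 1)), np.empty(0, dtype=int), np.array([0]), TreeConfig(), 2)


def test_predict_routing_and_boundary():
    x = np.array([[0.1], [0.2], [0.8], [0.9]])
    y = np.array([0, 0, 1, 1])
    tree = build_tree(x, y, np.array([0]), TreeConfig(), 2)
    left = tree_predict_proba(tree, np.array([0.15]))
    np.testing.assert_allclose(left, tree.left.proba)
    # exactly at the threshold routes left
    at = tree_predict_proba(tree, np.array([tree.threshold]))
    np.testing.assert_allclose(at, tree.left.proba)
    right = tree_predict_proba(tree, np.array([0.95]))
    np.testing.assert_allclose(right, tree.right.proba)


def test_predict_dimension_mismatch():
    x = np.array([[0.1, 0.0], [0.9, 0.0]])
    y = np.array([0, 1])
    tree = build_tree(x, y, np.array([0]), TreeConfig(), 2)
    with pytest.raises(ValueError, match="feature"):
        tree_predict_proba(tree, np.empty((1, 0)))


def test_tree_serialization_round_trip(rng):
    x = rng.random((30, 2))
    y = rng.integers(0, 2, 30)
    tree = build_tree(x, y, np.arange(2), TreeConfig(), 2)
    back = TreeNode.from_dict(tree.to_dict())
    grid = rng.random((20, 2))
    np.testing.assert_array_equal(tree_predict_proba(tree, grid), tree_predict_proba(back, grid))
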