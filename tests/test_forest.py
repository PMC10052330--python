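"""Weighted-forest training, feature subsampling, probability averaging."""

import numpy as np
import pytest
from scipy.stats import chisquare

from asvrf import (
    ForestConfig,
    TreeConfig,
    bootstrap_sample,
    default_t,
    forest_predict,
    forest_predict_proba,
    sample_features_weighted,
    train_asv_rf,
    tree_predict_proba,
)
from asvrf.forest import Forest
from conftest import make_dataset


def _separable(rng, n=200, n_features=4):
    y = rng.integers(0, 2, n)
    x = rng.standard_normal((n, n_features))
    x[:, 0] += np.where(y == 1, 2.0, -2.0)
    return make_dataset(x, y)


def test_bootstrap_determinism_and_shape():
    a = bootstrap_sample(50, np.random.default_rng(9))
    b = bootstrap_sample(50, np.random.default_rng(9))
    np.testing.assert_array_equal(a, b)
    assert a.shape == (50,)
    assert bootstrap_sample(1, np.random.default_rng(0)).tolist() == [0]
    with pytest.raises(ValueError):
        bootstrap_sample(0, np.random.default_rng(0))


def test_bootstrap_distinct_fraction(rng):
    """Distinct-row fraction concentrates near 1 - 1/e at N=1000."""
    fractions = [len(np.unique(bootstrap_sample(1000, rng))) / 1000 for _ in range(50)]
    assert np.mean(fractions) == pytest.approx(1 - np.exp(-1), abs=0.02)


@pytest.mark.parametrize("n_prime,expected", [(1, 1), (2, 2), (5, 3), (8, 4), (100, 7)])
def test_default_t(n_prime, expected):
    assert default_t(n_prime) == expected


def test_sample_features_uniform_when_weights_equal(rng):
    """Equal weights: inclusion frequencies pass a goodness-of-fit test."""
    counts = np.zeros(6)
    for _ in range(10_000):
        counts[sample_features_weighted(np.ones(6), 2, rng)] += 1
    # each draw includes 2 of 6 features; expected inclusion count is uniform
    assert chisquare(counts).pvalue > 0.01


def test_sample_features_heavily_biased(rng):
    wins = sum(sample_features_weighted(np.array([1.0, 1e6, 1.0]), 1, rng)[0] == 1 for _ in range(1000))
    assert wins >= 990


def test_sample_features_exhaustive_and_errors(rng):
    chosen = sample_features_weighted(np.array([0.0, 3.0, 1.0]), 3, rng)
    assert sorted(chosen) == [0, 1, 2]
    with pytest.raises(ValueError):
        sample_features_weighted(np.ones(3), 4, rng)


def test_train_rejects_single_class(rng):
    ds = make_dataset(rng.random((10, 2)), np.zeros(10, dtype=int), class_names=["a", "b"])
    with pytest.raises(ValueError, match="two classes"):
        train_asv_rf(ds, ForestConfig(k=2))


def test_train_deterministic_given_seed(rng):
    ds = _separable(rng, n=120)
    cfg = ForestConfig(k=5, beta=0.5, seed=42)
    f1 = train_asv_rf(ds, cfg)
    f2 = train_asv_rf(ds, cfg)
    assert f1.to_dict() == f2.to_dict()


def test_forest_structure_invariants(rng):
    ds = _separable(rng, n=150, n_features=8)
    cfg = ForestConfig(k=7, beta=0.5, seed=1)
    forest = train_asv_rf(ds, cfg)
    assert len(forest.trees) == 7
    n_prime = len(forest.selected_features)
    assert n_prime == 4  # round(0.5 * 8)
    t = default_t(n_prime)
    for subset in forest.feature_subsets:
        assert len(subset) == t
        assert len(set(subset.tolist())) == t
        assert set(subset.tolist()) <= set(forest.selected_features.tolist())


def test_k1_beta1_degenerates_to_single_tree(rng):
    ds = _separable(rng, n=80)
    cfg = ForestConfig(k=1, beta=1.0, t_override=ds.n_features, seed=5)
    forest = train_asv_rf(ds, cfg)
    grid = rng.standard_normal((30, ds.n_features))
    np.testing.assert_array_equal(
        forest_predict_proba(forest, grid), tree_predict_proba(forest.trees[0], grid)
    )


def test_predict_proba_is_mean_of_trees(rng):
    ds = _separable(rng, n=100)
    forest = train_asv_rf(ds, ForestConfig(k=4, seed=2))
    grid = rng.standard_normal((25, ds.n_features))
    per_tree = np.stack([tree_predict_proba(t, grid) for t in forest.trees])
    np.testing.assert_allclose(forest_predict_proba(forest, grid), per_tree.mean(axis=0), atol=1e-12)
    # convex combination: bounded by per-tree extremes, sums to one
    proba = forest_predict_proba(forest, grid)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(proba >= per_tree.min(axis=0) - 1e-12)
    assert np.all(proba <= per_tree.max(axis=0) + 1e-12)


def test_predict_label_argmax_tie_to_lower_index():
    from asvrf.tree import TreeNode
    from asvrf.weighting import FeatureWeights

    leaf = TreeNode(proba=np.array([0.5, 0.5]), count=2)
    cfg = ForestConfig(k=1)
    forest = Forest(
        trees=[leaf], feature_subsets=[np.array([0])],
        weights=FeatureWeights(np.array([1.0]), np.array([0]), [np.array([])]),
        selected_features=np.array([0]), class_names=["n", "p"], config=cfg, tree_seeds=[0],
    )
    assert forest_predict(forest, np.array([[0.3]]))[0] == 0


def test_oob_accuracy_reported(rng):
    ds = _separable(rng, n=200)
    forest = train_asv_rf(ds, ForestConfig(k=10, seed=3))
    assert forest.oob_accuracy is not None
    assert 0.5 < forest.oob_accuracy <= 1.0


def test_empty_forest_prediction_rejected():
    from asvrf.weighting import FeatureWeights

    with pytest.raises(ValueError):
        cfg = ForestConfig(k=1)
        f = Forest(trees=[], feature_subsets=[], weights=FeatureWeights(np.array([1.0]), np.array([0]), [np.array([])]),
                   selected_features=np.array([0]), class_names=["a", "b"], config=cfg, tree_seeds=[])


def test_per_node_sampling_variant_trains(rng):
    ds = _separable(rng, n=100, n_features=6)
    forest = train_asv_rf(ds, ForestConfig(k=3, seed=4, per_node_sampling=True))
    acc = np.mean(forest_predict(forest, ds.features) == ds.labels)
    assert acc > 0.8
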