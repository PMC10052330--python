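"""Chi-squared-weighted random forest of C4.5 trees (ASV-RF).

Training follows a fixed recipe: (1) weight every feature by its
chi-squared association with the class label, (2) sort features by weight,
(3) keep the top n' = max(1, round(beta * n)) features, then (4) grow k
C4.5 trees, each on its own bootstrap of the training rows and on t
features drawn from the retained set without replacement, biased toward
high weights, where t = floor(log2 n') + 1 capped at n'. Unlike the classic
random forest the feature subset is drawn once per tree (a per-node variant
is available for comparison). Prediction averages the per-tree leaf
probabilities,

    P(c_i | x) = (1/k) * sum_j P(c_i | x, h_j),

and the label is the argmax, ties resolved toward the lower class index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import Dataset
from .tree import TreeConfig, TreeNode, build_tree, tree_predict_proba
from .weighting import FeatureWeights, compute_feature_weights, rank_and_select

__all__ = [
    "ForestConfig",
    "Forest",
    "bootstrap_sample",
    "default_t",
    "sample_features_weighted",
    "train_asv_rf",
    "forest_predict_proba",
    "forest_predict",
]

_WEIGHT_FLOOR = 1e-12  # keeps zero-weight features selectable


@dataclass
class ForestConfig:
    k: int = 50
    beta: float = 0.5
    t_override: int | None = None
    seed: int = 0
    tree: TreeConfig = field(default_factory=TreeConfig)
    bins: int = 5
    per_node_sampling: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "k": self.k, "beta": self.beta, "t_override": self.t_override, "seed": self.seed,
            "tree": self.tree.to_dict(), "bins": self.bins, "per_node_sampling": self.per_node_sampling,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForestConfig":
        d = dict(d)
        d["tree"] = TreeConfig.from_dict(d["tree"])
        return cls(**d)


@dataclass
class Forest:
    """Trained ensemble: k trees, their feature subsets, and the weights used."""

    trees: list[TreeNode]
    feature_subsets: list[np.ndarray]
    weights: FeatureWeights
    selected_features: np.ndarray
    class_names: list[str]
    config: ForestConfig
    tree_seeds: list[int]
    oob_accuracy: float | None = None

    def __post_init__(self) -> None:
        if len(self.trees) != self.config.k:
            raise ValueError("forest must hold exactly k trees")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def to_dict(self) -> dict:
        return {
            "trees": [t.to_dict() for t in self.trees],
            "feature_subsets": [np.asarray(s).tolist() for s in self.feature_subsets],
            "weights": self.weights.to_dict(),
            "selected_features": np.asarray(self.selected_features).tolist(),
            "class_names": list(self.class_names),
            "config": self.config.to_dict(),
            "tree_seeds": list(self.tree_seeds),
            "oob_accuracy": self.oob_accuracy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Forest":
        return cls(
            trees=[TreeNode.from_dict(t) for t in d["trees"]],
            feature_subsets=[np.array(s, dtype=np.int64) for s in d["feature_subsets"]],
            weights=FeatureWeights.from_dict(d["weights"]),
            selected_features=np.array(d["selected_features"], dtype=np.int64),
            class_names=list(d["class_names"]),
            config=ForestConfig.from_dict(d["config"]),
            tree_seeds=list(d["tree_seeds"]),
            oob_accuracy=d.get("oob_accuracy"),
        )


def bootstrap_sample(n: int, rng: np.random.Generator) -> np.ndarray:
    """Row indices of a bootstrap: n draws uniformly with replacement."""
    if n < 1:
        raise ValueError("cannot bootstrap an empty dataset")
    return rng.integers(0, n, size=n)


def default_t(n_prime: int) -> int:
    """Per-tree feature-subset size: floor(log2 n') + 1, capped at n'."""
    if n_prime < 1:
        raise ValueError("n_prime must be at least 1")
    return min(int(math.floor(math.log2(n_prime))) + 1, n_prime)


def sample_features_weighted(weights: np.ndarray, t: int, rng: np.random.Generator) -> np.ndarray:
    """Draw t distinct indices, sequentially, with probability ~ weight.

    A tiny floor is added so zero-weight entries remain reachable when t
    approaches the pool size.
    """
    weights = np.asarray(weights, dtype=float)
    n = len(weights)
    if t > n:
        raise ValueError(f"cannot draw {t} distinct features from {n}")
    w = weights + _WEIGHT_FLOOR
    remaining = np.arange(n)
    chosen = np.empty(t, dtype=np.int64)
    for i in range(t):
        p = w[remaining]
        idx = rng.choice(len(remaining), p=p / p.sum())
        chosen[i] = remaining[idx]
        remaining = np.delete(remaining, idx)
    return chosen


def train_asv_rf(train: Dataset, cfg: ForestConfig) -> Forest:
    """Fit the weighted forest on a complete, labelled training set."""
    train.validate_for_training()
    train.require_complete()
    a = train.n_classes
    weights = compute_feature_weights(train, bins=cfg.bins)
    selected = rank_and_select(weights, cfg.beta, train.n_features)
    n_prime = len(selected)
    t = cfg.t_override if cfg.t_override is not None else default_t(n_prime)
    if t > n_prime:
        raise ValueError(f"t={t} exceeds the {n_prime} selected features")
    sel_weights = weights.weights[selected]
    x = train.features
    y = train.labels
    n = train.n_samples
    root_ss = np.random.SeedSequence(cfg.seed)
    tree_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in root_ss.spawn(cfg.k)]
    trees: list[TreeNode] = []
    subsets: list[np.ndarray] = []
    oob_votes = np.zeros((n, a))
    oob_counts = np.zeros(n)
    for seed in tree_seeds:
        rng = np.random.default_rng(seed)
        rows = bootstrap_sample(n, rng)
        if cfg.per_node_sampling:
            subset = selected  # nominal; resampled at each node
            sampler = lambda: selected[sample_features_weighted(sel_weights, t, rng)]
        else:
            subset = selected[sample_features_weighted(sel_weights, t, rng)]
            sampler = None
        tree = build_tree(x[rows], y[rows], subset, cfg.tree, a, feature_sampler=sampler)
        trees.append(tree)
        subsets.append(np.asarray(subset, dtype=np.int64))
        in_bag = np.zeros(n, dtype=bool)
        in_bag[rows] = True
        oob = np.flatnonzero(~in_bag)
        if len(oob):
            oob_votes[oob] += tree_predict_proba(tree, x[oob])
            oob_counts[oob] += 1
    covered = oob_counts > 0
    oob_accuracy = None
    if covered.any():
        oob_pred = np.argmax(oob_votes[covered], axis=1)
        oob_accuracy = float(np.mean(oob_pred == y[covered]))
    return Forest(
        trees=trees, feature_subsets=subsets, weights=weights, selected_features=selected,
        class_names=list(train.class_names), config=cfg, tree_seeds=tree_seeds,
        oob_accuracy=oob_accuracy,
    )


def forest_predict_proba(forest: Forest, x: np.ndarray) -> np.ndarray:
    """Probability-averaged ensemble estimate for one vector or a batch."""
    if not forest.trees:
        raise ValueError("empty forest")
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    acc = np.zeros((len(x), forest.n_classes))
    for tree in forest.trees:
        acc += tree_predict_proba(tree, x)
    acc /= len(forest.trees)
    return acc[0] if single else acc


def forest_predict(forest: Forest, x: np.ndarray) -> np.ndarray:
    """Argmax of the averaged probabilities; ties go to the lower class index."""
    proba = forest_predict_proba(forest, x)
    if proba.ndim == 1:
        return int(np.argmax(proba))
    return np.argmax(proba, axis=1)
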