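"""C4.5-style decision-tree induction with gain-ratio splits.

Trees are grown on continuous features (everything is numeric after
normalization or LDA projection), so every internal node is a binary
threshold test ``x[feature] <= threshold`` routing left. The split chosen at
a node maximizes the gain ratio — information gain divided by the entropy of
the partition sizes — over all candidate features and all midpoints between
consecutive distinct sorted values, subject to the C4.5 guard that the raw
information gain must be strictly positive. Leaves store Laplace-smoothed
class frequencies (count_i + 1) / (count + a), the per-tree probability
estimates averaged by the forest. No pruning is applied by default: the
trees serve as low-bias ensemble members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TreeNode", "TreeConfig", "entropy", "best_split", "build_tree", "tree_predict_proba"]

_GAIN_EPS = 1e-12  # information gain must strictly exceed zero


@dataclass
class TreeConfig:
    min_samples_leaf: int = 1
    max_depth: int | None = None
    min_gain_ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be at least 1")

    def to_dict(self) -> dict:
        return {"min_samples_leaf": self.min_samples_leaf, "max_depth": self.max_depth, "min_gain_ratio": self.min_gain_ratio}

    @classmethod
    def from_dict(cls, d: dict) -> "TreeConfig":
        return cls(**d)


@dataclass
class TreeNode:
    """Internal node (feature, threshold, children) or leaf (proba, count)."""

    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    proba: np.ndarray | None = None
    count: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.proba is not None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"proba": np.asarray(self.proba).tolist(), "count": self.count}
        return {
            "feature": int(self.feature),
            "threshold": float(self.threshold),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "proba" in d:
            return cls(proba=np.array(d["proba"], dtype=float), count=int(d["count"]))
        return cls(
            feature=int(d["feature"]), threshold=float(d["threshold"]),
            left=cls.from_dict(d["left"]), right=cls.from_dict(d["right"]),
        )

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()


def entropy(labels: np.ndarray) -> float:
    """Shannon entropy in bits of a class-label vector, with 0*log0 = 0."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    counts = np.bincount(labels.astype(np.int64))
    return _entropy_from_counts(counts.astype(float), float(labels.size))


def _entropy_from_counts(counts: np.ndarray, total: float) -> float:
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _row_entropies(count_rows: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Entropy of each row of class counts (rows may contain zeros)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p = count_rows / totals[:, None]
        terms = np.where(count_rows > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1)


def best_split(
    x: np.ndarray,
    y: np.ndarray,
    candidate_features: np.ndarray,
    cfg: TreeConfig,
    n_classes: int,
) -> tuple[int, float, float] | None:
    """Exhaustive gain-ratio maximization over candidate features.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values of each feature. Ties are broken toward the lower feature index,
    then the lower threshold. Returns (feature, threshold, gain_ratio), or
    None when no split has positive information gain, satisfies
    ``min_samples_leaf`` on both sides, and reaches ``min_gain_ratio``.
    """
    candidate_features = np.asarray(candidate_features, dtype=np.int64)
    if candidate_features.size == 0:
        raise ValueError("candidate feature list is empty")
    n = len(y)
    if n < 2:
        return None
    parent_counts = np.bincount(y, minlength=n_classes).astype(float)
    parent_entropy = _entropy_from_counts(parent_counts, float(n))
    onehot = np.zeros((n, n_classes))
    best: tuple[int, float, float] | None = None
    for f in sorted(int(f) for f in set(candidate_features.tolist())):
        v = x[:, f]
        order = np.argsort(v, kind="stable")
        sv = v[order]
        onehot[:] = 0.0
        onehot[np.arange(n), y[order]] = 1.0
        left_counts = np.cumsum(onehot, axis=0)
        nl = np.arange(1, n, dtype=float)
        # split after position i is admissible only between distinct values
        valid = sv[:-1] < sv[1:]
        valid &= (nl >= cfg.min_samples_leaf) & (n - nl >= cfg.min_samples_leaf)
        if not valid.any():
            continue
        idx = np.flatnonzero(valid)
        lc = left_counts[idx]
        rc = parent_counts[None, :] - lc
        nls = nl[idx]
        nrs = n - nls
        child = (nls * _row_entropies(lc, nls) + nrs * _row_entropies(rc, nrs)) / n
        gain = parent_entropy - child
        pl = nls / n
        split_entropy = -(pl * np.log2(pl) + (1 - pl) * np.log2(1 - pl))
        with np.errstate(invalid="ignore", divide="ignore"):
            gain_ratio = gain / split_entropy
        ok = (gain > _GAIN_EPS) & (split_entropy > 0) & (gain_ratio >= cfg.min_gain_ratio)
        if not ok.any():
            continue
        gain_ratio = np.where(ok, gain_ratio, -np.inf)
        k = int(np.argmax(gain_ratio))  # first max -> lowest threshold
        gr = float(gain_ratio[k])
        if best is None or gr > best[2]:
            threshold = float((sv[idx[k]] + sv[idx[k] + 1]) / 2.0)
            best = (f, threshold, gr)
    return best


def build_tree(
    x: np.ndarray,
    y: np.ndarray,
    candidate_features: np.ndarray,
    cfg: TreeConfig,
    n_classes: int,
    feature_sampler=None,
) -> TreeNode:
    """Grow a tree by recursive partitioning (iterative, so depth is unbounded).

    A node becomes a leaf when it is pure, holds fewer than
    ``2 * min_samples_leaf`` rows, sits at ``max_depth``, or admits no split.
    ``feature_sampler``, when given, is called per node to redraw the
    candidate features (per-node subspace sampling, Breiman-style); otherwise
    the fixed per-tree candidate set is used everywhere.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if len(y) == 0:
        raise ValueError("cannot build a tree from an empty training set")
    candidate_features = np.asarray(candidate_features, dtype=np.int64)
    root = TreeNode()
    stack: list[tuple[TreeNode, np.ndarray, int]] = [(root, np.arange(len(y)), 0)]
    while stack:
        node, rows, depth = stack.pop()
        ys = y[rows]
        counts = np.bincount(ys, minlength=n_classes).astype(float)
        pure = np.count_nonzero(counts) <= 1
        at_depth = cfg.max_depth is not None and depth >= cfg.max_depth
        too_small = len(rows) < 2 * cfg.min_samples_leaf
        split = None
        if not (pure or at_depth or too_small):
            feats = feature_sampler() if feature_sampler is not None else candidate_features
            split = best_split(x[rows], ys, feats, cfg, n_classes)
        if split is None:
            node.proba = (counts + 1.0) / (counts.sum() + n_classes)
            node.count = len(rows)
            continue
        f, threshold, _ = split
        node.feature = f
        node.threshold = threshold
        go_left = x[rows, f] <= threshold
        node.left = TreeNode()
        node.right = TreeNode()
        stack.append((node.left, rows[go_left], depth + 1))
        stack.append((node.right, rows[~go_left], depth + 1))
    return root


def tree_predict_proba(tree: TreeNode, x: np.ndarray) -> np.ndarray:
    """Class-probability estimates for one vector or a batch of rows."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    n_classes = _leaf_width(tree)
    out = np.empty((len(x), n_classes))
    _route(tree, x, np.arange(len(x)), out)
    return out[0] if single else out


def _leaf_width(tree: TreeNode) -> int:
    while not tree.is_leaf:
        tree = tree.left
    return len(tree.proba)


def _route(root: TreeNode, x: np.ndarray, rows: np.ndarray, out: np.ndarray) -> None:
    stack = [(root, rows)]
    while stack:
        node, rows = stack.pop()
        if node.is_leaf:
            out[rows] = node.proba
            continue
        if node.feature >= x.shape[1]:
            raise ValueError(f"tree tests feature {node.feature} but input has {x.shape[1]} features")
        go_left = x[rows, node.feature] <= node.threshold
        if go_left.any():
            stack.append((node.left, rows[go_left]))
        if (~go_left).any():
            stack.append((node.right, rows[~go_left]))
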