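"""Chi-squared feature weighting, ranking, and top-beta*n selection.

Each feature's weight is the chi-squared statistic of its contingency table
against the class label,

    chi2 = sum_i sum_j (O_ij - e_ij)^2 / e_ij,   e_ij = row_i * col_j / N,

with empty-expectation cells contributing zero (they arise when a level or a
class is absent from a bootstrap). Continuous features are discretized by
equal-frequency binning fit on training data; a high weight marks a feature
whose level distribution differs between classes. The forest keeps the
n' = max(1, round(beta*n)) top-weighted features and biases per-tree feature
subsampling toward high weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset

__all__ = [
    "ContingencyTable",
    "FeatureWeights",
    "discretize_feature",
    "chi_squared_weight",
    "compute_feature_weights",
    "rank_and_select",
]


@dataclass
class ContingencyTable:
    observed: np.ndarray  # m levels x a classes
    expected: np.ndarray
    total: int


@dataclass
class FeatureWeights:
    """Per-feature chi-squared scores, decreasing rank order, and bin edges."""

    weights: np.ndarray
    rank_order: np.ndarray
    bin_edges: list[np.ndarray]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.rank_order = np.asarray(self.rank_order, dtype=np.int64)
        if np.any(self.weights < 0):
            raise ValueError("chi-squared weights must be non-negative")

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "rank_order": self.rank_order.tolist(),
            "bin_edges": [e.tolist() for e in self.bin_edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureWeights":
        return cls(
            weights=np.array(d["weights"]),
            rank_order=np.array(d["rank_order"]),
            bin_edges=[np.array(e) for e in d["bin_edges"]],
        )


def discretize_feature(
    values: np.ndarray, bins: int = 5, edges: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-frequency discretization into at most ``bins`` levels.

    Interior edges are the 1/bins .. (bins-1)/bins quantiles with duplicates
    merged, so skewed or heavily tied features degrade gracefully (down to a
    single level for a constant vector). Pass the returned ``edges`` back in
    to code test-time values with the training bins.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if edges is None:
        if bins < 2:
            raise ValueError("bins must be at least 2")
        qs = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
        edges = np.unique(qs)
    else:
        edges = np.asarray(edges, dtype=float)
    codes = np.searchsorted(edges, values, side="left")
    return codes.astype(np.int64), edges


def chi_squared_weight(codes: np.ndarray, labels: np.ndarray) -> tuple[float, ContingencyTable]:
    """Chi-squared statistic of a discrete feature against the class label."""
    codes = np.asarray(codes)
    labels = np.asarray(labels)
    if codes.shape != labels.shape:
        raise ValueError("codes and labels must have the same length")
    n = len(codes)
    if n < 1:
        raise ValueError("empty input")
    level_values, level_idx = np.unique(codes, return_inverse=True)
    class_values, class_idx = np.unique(labels, return_inverse=True)
    m, a = len(level_values), len(class_values)
    observed = np.zeros((m, a))
    np.add.at(observed, (level_idx, class_idx), 1.0)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row * col / n
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (observed - expected) ** 2 / expected
    terms[expected == 0] = 0.0
    chi2 = float(terms.sum())
    return chi2, ContingencyTable(observed=observed, expected=expected, total=n)


def compute_feature_weights(ds: Dataset, bins: int = 5) -> FeatureWeights:
    """Weight every feature of a complete dataset; rank by decreasing weight.

    Ties in weight are broken by ascending feature index so the ranking is
    reproducible.
    """
    ds.require_complete()
    weights = np.empty(ds.n_features)
    all_edges: list[np.ndarray] = []
    for j in range(ds.n_features):
        codes, edges = discretize_feature(ds.features[:, j], bins=bins)
        weights[j], _ = chi_squared_weight(codes, ds.labels)
        all_edges.append(edges)
    order = np.lexsort((np.arange(ds.n_features), -weights))
    return FeatureWeights(weights=weights, rank_order=order, bin_edges=all_edges)


def rank_and_select(weights: FeatureWeights, beta: float, n: int | None = None) -> np.ndarray:
    """Top ``n' = max(1, round(beta*n))`` feature indices, in rank order."""
    if not 0.0 < beta <= 1.0:
        raise ValueError("beta must lie in (0, 1]")
    if n is None:
        n = len(weights.weights)
    n_prime = max(1, int(round(beta * n)))
    return weights.rank_order[:n_prime].copy()
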