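"""Linear discriminant analysis as a supervised feature extractor.

The discriminant basis W maximizes the Fisher criterion: the ratio of
between-class scatter

    S_C = sum_k M_k (mu_k - mu)(mu_k - mu)^T

to within-class scatter

    S_V = sum_k sum_{x in X_k} (x - mu_k)(x - mu_k)^T,

obtained by solving the generalized eigenproblem S_C w = psi (S_V + r I) w.
The Tikhonov ridge r (default 1e-6 * trace(S_V)/n) keeps the problem
well-posed when S_V is singular, which happens routinely with few samples
or collinear features. At most a-1 eigenvalues can be strictly positive,
so the subspace dimension L is capped at min(n, a-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .data import Dataset

__all__ = ["LDAModel", "scatter_matrices", "fit_lda", "project"]


@dataclass
class LDAModel:
    """Discriminant subspace: basis W (n x L, unit columns), eigenvalues (decreasing)."""

    W: np.ndarray
    eigenvalues: np.ndarray
    class_means: np.ndarray
    global_mean: np.ndarray
    L: int

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.W.shape[1] != self.L or len(self.eigenvalues) != self.L:
            raise ValueError("basis/eigenvalue count must equal L")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be sorted non-increasing")

    def to_dict(self) -> dict:
        return {
            "W": self.W.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "class_means": np.asarray(self.class_means).tolist(),
            "global_mean": np.asarray(self.global_mean).tolist(),
            "L": self.L,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LDAModel":
        return cls(
            W=np.array(d["W"]), eigenvalues=np.array(d["eigenvalues"]),
            class_means=np.array(d["class_means"]), global_mean=np.array(d["global_mean"]), L=d["L"],
        )


def scatter_matrices(ds: Dataset) -> tuple[np.ndarray, np.ndarray]:
    """Between-class and within-class scatter matrices (S_C, S_V)."""
    ds.require_complete()
    x = ds.features
    mu = x.mean(axis=0)
    n = ds.n_features
    s_c = np.zeros((n, n))
    s_v = np.zeros((n, n))
    for c in range(ds.n_classes):
        xk = x[ds.labels == c]
        if len(xk) == 0:
            raise ValueError(f"class {ds.class_names[c]!r} has no members")
        mu_k = xk.mean(axis=0)
        d = mu_k - mu
        s_c += len(xk) * np.outer(d, d)
        centered = xk - mu_k
        s_v += centered.T @ centered
    return s_c, s_v


def fit_lda(ds: Dataset, L: int | None = None, ridge: float | None = None) -> LDAModel:
    """Fit the discriminant basis from labelled, preprocessed data.

    Parameters
    ----------
    L : int, optional
        Subspace dimension; defaults to min(a-1, n), the maximal number of
        informative discriminant directions.
    ridge : float, optional
        Tikhonov regularizer added to S_V; defaults to 1e-6 * trace(S_V)/n.
    """
    ds.validate_for_training()
    n = ds.n_features
    a = ds.n_classes
    max_l = min(n, a - 1)
    if L is None:
        L = max_l
    if not 1 <= L <= max_l:
        raise ValueError(f"L must lie in [1, min(n, a-1)] = [1, {max_l}]; got {L}")
    s_c, s_v = scatter_matrices(ds)
    if ridge is None:
        ridge = 1e-6 * np.trace(s_v) / n
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    b = s_v + ridge * np.eye(n)
    try:
        eigvals, eigvecs = scipy.linalg.eigh(s_c, b)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            "within-class scatter is numerically singular even after regularization; raise the ridge parameter"
        ) from exc
    order = np.argsort(eigvals)[::-1][:L]
    w = eigvecs[:, order]
    psi = eigvals[order]
    # unit columns with a deterministic sign: largest-magnitude component positive
    w = w / np.linalg.norm(w, axis=0, keepdims=True)
    for k in range(L):
        lead = np.argmax(np.abs(w[:, k]))
        if w[lead, k] < 0:
            w[:, k] = -w[:, k]
    mu = ds.features.mean(axis=0)
    means = np.vstack([ds.features[ds.labels == c].mean(axis=0) for c in range(a)])
    return LDAModel(W=w, eigenvalues=psi, class_means=means, global_mean=mu, L=L)


def project(model: LDAModel, ds: Dataset) -> Dataset:
    """Project rows into the discriminant subspace: features become W^T x."""
    if ds.n_features != model.W.shape[0]:
        raise ValueError(f"dimension mismatch: model expects {model.W.shape[0]} features, data has {ds.n_features}")
    z = ds.features @ model.W
    return Dataset(
        features=z,
        labels=ds.labels.copy(),
        feature_names=[f"ld{k + 1}" for k in range(model.L)],
        class_names=list(ds.class_names),
        missing=np.zeros_like(z, dtype=bool),
    )
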