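"""Tabular dataset container, CSV I/O, deterministic splitting.

A :class:`Dataset` is the currency passed between every pipeline stage: an
``N x n`` float matrix with an explicit missingness mask, integer-coded class
labels, and the feature / class names needed to keep CSV round trips and
model schemas honest. Missing cells are masked rather than encoded by a
sentinel value so that downstream scatter and chi-squared computations can
never silently absorb placeholder numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset", "SplitPair", "read_csv_dataset", "write_csv_dataset", "split_dataset"]


@dataclass
class Dataset:
    """Feature matrix + labels + names.

    Parameters
    ----------
    features : ndarray, shape (N, n)
        Real-valued feature matrix. Entries flagged in ``missing`` carry NaN.
    labels : ndarray of int, shape (N,)
        Dense class codes ``0..a-1`` indexing into ``class_names``.
    feature_names : list of str
    class_names : list of str
        Class label strings, in first-seen order (deterministic encoding).
    missing : ndarray of bool, shape (N, n)
        True where the entry is missing.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    class_names: list[str]
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.missing is None:
            self.missing = np.isnan(self.features)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
        n_samples, n_features = self.features.shape
        if self.labels.shape != (n_samples,):
            raise ValueError("labels length must match number of rows")
        if self.missing.shape != self.features.shape:
            raise ValueError("missing mask shape must match features")
        if len(self.feature_names) != n_features:
            raise ValueError("feature_names length must match number of columns")
        if len(set(self.feature_names)) != n_features:
            raise ValueError("feature_names must be unique")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValueError("labels reference undeclared classes")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, rows: np.ndarray) -> "Dataset":
        """Row-indexed view (copy) keeping names and class coding."""
        rows = np.asarray(rows)
        return Dataset(
            features=self.features[rows].copy(),
            labels=self.labels[rows].copy(),
            feature_names=list(self.feature_names),
            class_names=list(self.class_names),
            missing=self.missing[rows].copy(),
        )

    def require_complete(self) -> None:
        if self.missing.any():
            raise ValueError("operation requires a dataset without missing values; run preprocessing first")

    def validate_for_training(self) -> None:
        if self.n_samples < 1 or self.n_features < 1:
            raise ValueError("training requires at least one row and one feature")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("training requires at least two classes present")


@dataclass
class SplitPair:
    train: Dataset
    test: Dataset
    seed: int


def read_csv_dataset(path: str, label_column: str, missing_token: str = "NA") -> Dataset:
    """Read an RFC-4180 CSV (header required) into a Dataset.

    Cells equal to ``missing_token`` (or empty) become masked entries; any
    other non-numeric feature cell is an error. Class labels are taken
    verbatim as strings and coded in first-seen order.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in header")
    if len(df) == 0:
        raise ValueError("CSV contains no data rows")
    feature_names = [c for c in df.columns if c != label_column]
    if not feature_names:
        raise ValueError("CSV contains no feature columns")
    raw = df[feature_names].to_numpy(dtype=object)
    missing = (raw == missing_token) | (raw == "")
    features = np.empty(raw.shape, dtype=float)
    features[missing] = np.nan
    present = ~missing
    try:
        features[present] = raw[present].astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric feature cell encountered: {exc}") from exc
    label_strings = df[label_column].tolist()
    class_names: list[str] = []
    codes = np.empty(len(label_strings), dtype=np.int64)
    index: dict[str, int] = {}
    for i, s in enumerate(label_strings):
        if s not in index:
            index[s] = len(class_names)
            class_names.append(s)
        codes[i] = index[s]
    return Dataset(features=features, labels=codes, feature_names=feature_names, class_names=class_names, missing=missing)


def write_csv_dataset(ds: Dataset, path: str, label_column: str = "label", missing_token: str = "NA") -> None:
    """Inverse of :func:`read_csv_dataset`; read(write(ds)) is a fixed point."""
    if label_column in ds.feature_names:
        raise ValueError(f"label column name {label_column!r} collides with a feature name")
    cols = {}
    for j, name in enumerate(ds.feature_names):
        col = np.array([repr(float(v)) for v in ds.features[:, j]], dtype=object)
        col[ds.missing[:, j]] = missing_token
        cols[name] = col
    cols[label_column] = [ds.class_names[c] for c in ds.labels]
    pd.DataFrame(cols).to_csv(path, index=False)


def split_dataset(ds: Dataset, test_fraction: float, seed: int, stratified: bool = True) -> SplitPair:
    """Partition rows into train/test; identical seed reproduces the split.

    ``|test| = round(test_fraction * N)``. Under stratification the test set
    takes ``round(test_fraction * N_c)`` rows of each class c, so per-class
    proportions are preserved within rounding.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    n = ds.n_samples
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    if stratified:
        test_idx: list[np.ndarray] = []
        for c in range(ds.n_classes):
            rows = np.flatnonzero(ds.labels == c)
            if len(rows) == 0:
                continue
            if len(rows) < 2:
                raise ValueError(f"class {ds.class_names[c]!r} has fewer than 2 members; cannot stratify")
            k = int(round(test_fraction * len(rows)))
            k = min(max(k, 1), len(rows) - 1)
            test_idx.append(rng.permutation(rows)[:k])
        test_rows = np.sort(np.concatenate(test_idx))
    else:
        k = int(round(test_fraction * n))
        k = min(max(k, 1), n - 1)
        test_rows = np.sort(rng.permutation(n)[:k])
    mask = np.zeros(n, dtype=bool)
    mask[test_rows] = True
    return SplitPair(train=ds.subset(np.flatnonzero(~mask)), test=ds.subset(test_rows), seed=seed)
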