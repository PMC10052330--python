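"""Missing-value imputation and min-max normalization.

Statistics (per-feature extremes and imputation values) are fit on the
training split only and then applied to any compatible dataset, so no
information leaks from test data into the transform. Each value x of a
feature with training range [d_min, d_max] maps to

    (x - d_min) / (d_max - d_min) * (new_max - new_min) + new_min

after missing entries are replaced by the per-feature training median (or
mean). Constant features (d_max == d_min) map to new_min; out-of-range
test-time values are clipped into [new_min, new_max] by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Dataset

__all__ = ["NormalizationParams", "fit_preprocessor", "apply_preprocessor"]


@dataclass
class NormalizationParams:
    d_min: np.ndarray
    d_max: np.ndarray
    impute_values: np.ndarray
    new_min: float = 0.0
    new_max: float = 1.0
    impute: str = "median"
    clip: bool = True
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d_min = np.asarray(self.d_min, dtype=float)
        self.d_max = np.asarray(self.d_max, dtype=float)
        self.impute_values = np.asarray(self.impute_values, dtype=float)
        if np.any(self.d_min > self.d_max):
            raise ValueError("d_min must not exceed d_max")
        if not self.new_min < self.new_max:
            raise ValueError("new_min must be strictly below new_max")

    def to_dict(self) -> dict:
        return {
            "d_min": self.d_min.tolist(),
            "d_max": self.d_max.tolist(),
            "impute_values": self.impute_values.tolist(),
            "new_min": self.new_min,
            "new_max": self.new_max,
            "impute": self.impute,
            "clip": self.clip,
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(**{**d, "d_min": np.array(d["d_min"]), "d_max": np.array(d["d_max"]), "impute_values": np.array(d["impute_values"])})


def fit_preprocessor(
    train: Dataset,
    new_min: float = 0.0,
    new_max: float = 1.0,
    impute: str = "median",
    clip: bool = True,
) -> NormalizationParams:
    """Learn per-feature extremes and imputation values from training data.

    Raises if a feature has no observed training value, since neither an
    extreme nor an imputation value would be defined for it.
    """
    if impute not in ("median", "mean", "none"):
        raise ValueError("impute must be one of 'median', 'mean', 'none'")
    n = train.n_features
    d_min = np.empty(n)
    d_max = np.empty(n)
    fill = np.empty(n)
    for j in range(n):
        observed = train.features[~train.missing[:, j], j]
        if observed.size == 0:
            raise ValueError(f"feature {train.feature_names[j]!r} is entirely missing in training data")
        d_min[j] = observed.min()
        d_max[j] = observed.max()
        if impute == "median":
            fill[j] = float(np.median(observed))
        elif impute == "mean":
            fill[j] = float(observed.mean())
        else:
            fill[j] = np.nan
    return NormalizationParams(
        d_min=d_min, d_max=d_max, impute_values=fill,
        new_min=new_min, new_max=new_max, impute=impute, clip=clip,
        feature_names=list(train.feature_names),
    )


def apply_preprocessor(params: NormalizationParams, ds: Dataset) -> Dataset:
    """Impute then normalize; returns a complete (mask-free) Dataset."""
    if ds.n_features != len(params.d_min):
        raise ValueError(f"feature-count mismatch: transform fitted on {len(params.d_min)} features, data has {ds.n_features}")
    x = ds.features.copy()
    if params.impute != "none":
        for j in range(ds.n_features):
            x[ds.missing[:, j], j] = params.impute_values[j]
    elif ds.missing.any():
        raise ValueError("dataset has missing values but imputation is disabled")
    span = params.d_max - params.d_min
    out_span = params.new_max - params.new_min
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - params.d_min) / span * out_span + params.new_min
    # constant features: Eq is 0/0 there; pin to new_min deterministically
    constant = span == 0
    if constant.any():
        z[:, constant] = params.new_min
    if params.clip:
        np.clip(z, params.new_min, params.new_max, out=z)
    return Dataset(
        features=z,
        labels=ds.labels.copy(),
        feature_names=list(ds.feature_names),
        class_names=list(ds.class_names),
        missing=np.zeros_like(z, dtype=bool),
    )
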