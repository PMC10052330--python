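"""Synthetic e-health cohort generator with planted ground truth.

Emulates a continuous-glucose-monitoring style table: a cohort of patients,
each contributing many readings, with a handful of informative continuous
features, extra pure-noise features, and missing values scattered
completely at random. Class-conditional informative features are
equicorrelated Gaussians whose means differ by ``class_separation``
standard deviations per feature (half the shift on each side of zero), so
the Bayes-optimal error of the generative model is available in closed form
as an oracle for classifier sanity checks: with Mahalanobis distance Delta
between the class means the balanced-cohort optimum is Phi(-Delta/2).

Defaults mirror a cohort of 62 patients with roughly 203 readings each
(about 12.6k rows), 5 informative characteristics, 15 noise features,
separation 1.5, and 20% missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import norm

from .data import Dataset
from .rng import substream

__all__ = ["CohortSpec", "generate_cohort", "bayes_error", "mahalanobis_separation"]


@dataclass
class CohortSpec:
    n_patients: int = 62
    readings_per_patient: int = 203
    n_informative: int = 5
    n_noise: int = 15
    class_separation: float = 1.5
    class_balance: float = 0.5
    missing_rate: float = 0.2
    feature_correlation: float = 0.3
    patient_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValueError("need at least one informative feature")
        if self.n_noise < 0:
            raise ValueError("n_noise must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if not 0.0 <= self.feature_correlation < 1.0:
            raise ValueError("feature_correlation must lie in [0, 1)")
        if self.n_patients < 1 or self.readings_per_patient < 1:
            raise ValueError("cohort must contain at least one reading")
        if self.class_separation < 0:
            raise ValueError("class_separation must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def generate_cohort(spec: CohortSpec) -> tuple[Dataset, dict]:
    """Draw a cohort; identical spec (including seed) gives identical data.

    Returns the Dataset and a ground-truth record holding the informative
    feature indices and the generating parameters.
    """
    rng = substream(spec.seed, "simulate")
    n = spec.n_patients * spec.readings_per_patient
    f, q = spec.n_informative, spec.n_noise
    rho = spec.feature_correlation
    labels = (rng.random(n) < spec.class_balance).astype(np.int64)
    # equicorrelated unit-variance block: sqrt(rho)*shared + sqrt(1-rho)*own
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, f))
    informative = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
    shift = spec.class_separation / 2.0
    informative += np.where(labels[:, None] == 1, shift, -shift)
    if spec.patient_effect > 0:
        intercepts = spec.patient_effect * rng.standard_normal(spec.n_patients)
        patient = np.repeat(np.arange(spec.n_patients), spec.readings_per_patient)
        informative += intercepts[patient][:, None]
    noise = rng.standard_normal((n, q))
    features = np.concatenate([informative, noise], axis=1)
    missing = rng.random(features.shape) < spec.missing_rate
    features = features.copy()
    features[missing] = np.nan
    ds = Dataset(
        features=features,
        labels=labels,
        feature_names=[f"inf{i + 1}" for i in range(f)] + [f"noise{i + 1}" for i in range(q)],
        class_names=["normal", "alarming"],
        missing=missing,
    )
    truth = {
        "informative_features": list(range(f)),
        "spec": spec.to_dict(),
        "bayes_error": bayes_error(spec),
    }
    return ds, truth


def mahalanobis_separation(spec: CohortSpec) -> float:
    """Mahalanobis distance between the two class means.

    For an equicorrelated block (correlation rho, f features) with a shift
    of s per feature, Delta = s * sqrt(f / (1 - rho + rho * f)); noise
    features carry no shift and do not contribute.
    """
    f = spec.n_informative
    rho = spec.feature_correlation
    return spec.class_separation * np.sqrt(f / (1.0 - rho + rho * f))


def bayes_error(spec: CohortSpec) -> float:
    """Minimum achievable misclassification rate of the generative model.

    With standardized discriminant score u (N(0,1) under class 0, N(Delta,1)
    under class 1) and log prior odds g = ln(pi1/pi0), the optimal rule
    thresholds u at Delta/2 - g/Delta, giving
    pi0 * Phi(-(Delta/2 - g/Delta + ... )) — evaluated below; at balance this
    reduces to Phi(-Delta/2).
    """
    delta = mahalanobis_separation(spec)
    pi1 = spec.class_balance
    pi0 = 1.0 - pi1
    if delta == 0:
        return float(min(pi0, pi1))
    g = np.log(pi1 / pi0)
    theta = delta / 2.0 - g / delta
    return float(pi0 * norm.sf(theta) + pi1 * norm.cdf(theta - delta))
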