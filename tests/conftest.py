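import numpy as np
import pytest

from asvrf import Dataset


def make_dataset(features, labels, class_names=None, feature_names=None, missing=None):
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        names = []
        codes = []
        for s in labels:
            if s not in names:
                names.append(s)
            codes.append(names.index(s))
        class_names = class_names or names
        labels = np.array(codes)
    elif class_names is None:
        class_names = [f"c{i}" for i in range(int(labels.max()) + 1)]
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(features.shape[1])]
    return Dataset(features=features, labels=labels, feature_names=feature_names,
                   class_names=class_names, missing=missing)


@pytest.fixture
def toy_binary():
    """Linearly separable 4-point, 1-feature problem."""
    return make_dataset([[0.1], [0.2], [0.8], [0.9]], ["A", "A", "B", "B"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
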