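"""End-to-end orchestration: normalize -> extract -> classify -> evaluate.

The pipeline fixes the stage order (min-max normalization, optional LDA
projection, weighted-forest training) and fans a single global seed out to
the stochastic stages by name, so a config + seed pair fully determines the
trained model and every prediction. Chi-squared weighting operates on the
post-LDA feature space when LDA is enabled. Trained pipelines round-trip
through a versioned JSON document.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from .data import Dataset
from .forest import Forest, ForestConfig, forest_predict_proba, train_asv_rf
from .lda import LDAModel, fit_lda, project
from .metrics import MetricsReport, compute_metrics, confusion, mae_rmse
from .preprocess import NormalizationParams, apply_preprocessor, fit_preprocessor
from .pso import PSOConfig, tune_asvrf
from .rng import substream_seed
from .tree import TreeConfig

__all__ = ["PipelineConfig", "ModelBundle", "run_train", "run_evaluate", "save_model", "load_model"]

BUNDLE_FORMAT_VERSION = 1


def _merged(defaults: dict, given: dict | None) -> dict:
    out = dict(defaults)
    for k, v in (given or {}).items():
        if k not in defaults:
            raise ValueError(f"unknown config key {k!r}")
        out[k] = v
    return out


@dataclass
class PipelineConfig:
    seed: int = 0
    label_column: str = "label"
    missing_token: str = "NA"
    positive_class: str | None = None
    preprocess: dict = field(default_factory=dict)
    lda: dict = field(default_factory=dict)
    weighting: dict = field(default_factory=dict)
    forest: dict = field(default_factory=dict)
    tune: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.preprocess = _merged({"new_min": 0.0, "new_max": 1.0, "impute": "median", "clip": True}, self.preprocess)
        self.lda = _merged({"enabled": True, "L": None, "ridge": None}, self.lda)
        self.weighting = _merged({"bins": 5, "beta": 0.5}, self.weighting)
        self.forest = _merged(
            {"k": 50, "t": None, "per_node_sampling": False,
             "min_samples_leaf": 1, "max_depth": None, "min_gain_ratio": 0.0},
            self.forest,
        )
        self.tune = _merged(
            {"enabled": False, "folds": 3, "beta_range": [0.1, 1.0], "k_range": [5, 100],
             "np": 6, "iter_max": 8, "c1": 2.0, "c2": 2.0, "wmax": 0.9, "wmin": 0.4},
            self.tune,
        )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "label_column": self.label_column, "missing_token": self.missing_token,
            "positive_class": self.positive_class, "preprocess": self.preprocess, "lda": self.lda,
            "weighting": self.weighting, "forest": self.forest, "tune": self.tune,
        }

    def forest_config(self) -> ForestConfig:
        return ForestConfig(
            k=self.forest["k"],
            beta=self.weighting["beta"],
            t_override=self.forest["t"],
            seed=substream_seed(self.seed, "forest"),
            tree=TreeConfig(
                min_samples_leaf=self.forest["min_samples_leaf"],
                max_depth=self.forest["max_depth"],
                min_gain_ratio=self.forest["min_gain_ratio"],
            ),
            bins=self.weighting["bins"],
            per_node_sampling=self.forest["per_node_sampling"],
        )


@dataclass
class ModelBundle:
    """Everything needed to reproduce predictions: transform, subspace, forest."""

    normalizer: NormalizationParams
    lda: LDAModel | None
    forest: Forest
    config: PipelineConfig
    training_time_s: float | None = None

    def transform(self, ds: Dataset) -> Dataset:
        if list(ds.feature_names) != list(self.normalizer.feature_names):
            missing = set(self.normalizer.feature_names) - set(ds.feature_names)
            if missing:
                raise ValueError(f"dataset is missing feature column(s): {sorted(missing)}")
            raise ValueError("dataset feature columns do not match the trained schema (order matters)")
        out = apply_preprocessor(self.normalizer, ds)
        if self.lda is not None:
            out = project(self.lda, out)
        return out

    def predict_proba(self, ds: Dataset) -> np.ndarray:
        return forest_predict_proba(self.forest, self.transform(ds).features)

    def predict(self, ds: Dataset) -> list[str]:
        proba = self.predict_proba(ds)
        return [self.forest.class_names[i] for i in np.argmax(proba, axis=1)]


def run_train(config: PipelineConfig, train: Dataset, log=None) -> ModelBundle:
    """Fit the full pipeline on a training Dataset."""
    emit = log if log is not None else (lambda msg: None)
    t0 = time.perf_counter()
    train.validate_for_training()
    emit(f"preprocess: fitting min-max normalizer ({train.n_samples} rows, {train.n_features} features; "
         f"impute={config.preprocess['impute']})")
    normalizer = fit_preprocessor(
        train,
        new_min=config.preprocess["new_min"], new_max=config.preprocess["new_max"],
        impute=config.preprocess["impute"], clip=config.preprocess["clip"],
    )
    working = apply_preprocessor(normalizer, train)
    lda_model: LDAModel | None = None
    if config.lda["enabled"]:
        lda_model = fit_lda(working, L=config.lda["L"], ridge=config.lda["ridge"])
        emit(f"lda: L={lda_model.L}, leading eigenvalue {lda_model.eigenvalues[0]:.4g}")
        working = project(lda_model, working)
    forest_cfg = config.forest_config()
    if config.tune["enabled"]:
        emit("pso: tuning (beta, k) by cross-validated error")
        pso_cfg = PSOConfig(
            bounds=[(0.0, 1.0)],  # replaced inside tune_asvrf
            n_particles=config.tune["np"], iter_max=config.tune["iter_max"],
            c1=config.tune["c1"], c2=config.tune["c2"],
            w_max=config.tune["wmax"], w_min=config.tune["wmin"],
            seed=substream_seed(config.seed, "pso"),
        )
        forest_cfg, cv_error = tune_asvrf(
            working,
            beta_range=tuple(config.tune["beta_range"]), k_range=tuple(config.tune["k_range"]),
            folds=config.tune["folds"], pso_cfg=pso_cfg, base_cfg=forest_cfg,
        )
        emit(f"pso: tuned beta={forest_cfg.beta:.3f}, k={forest_cfg.k} (CV error {cv_error:.4f})")
    forest = train_asv_rf(working, forest_cfg)
    elapsed = time.perf_counter() - t0
    emit(f"forest: trained k={forest_cfg.k} trees, beta={forest_cfg.beta}, "
         f"seed={forest_cfg.seed}, oob_accuracy={forest.oob_accuracy}")
    emit(f"training completed in {elapsed:.3f} s")
    return ModelBundle(normalizer=normalizer, lda=lda_model, forest=forest, config=config, training_time_s=elapsed)


def run_evaluate(bundle: ModelBundle, test: Dataset, positive_class: str | None = None) -> MetricsReport:
    """Apply the stored pipeline to a test Dataset and score the predictions."""
    if positive_class is None:
        positive_class = bundle.config.positive_class
    if positive_class is None:
        positive_class = bundle.forest.class_names[-1]
    if positive_class not in bundle.forest.class_names:
        raise ValueError(f"positive class {positive_class!r} unknown to the model")
    proba = bundle.predict_proba(test)
    pred = np.array([bundle.forest.class_names[i] for i in np.argmax(proba, axis=1)])
    truth = np.array([test.class_names[c] for c in test.labels])
    cm = confusion(truth, pred, positive_class)
    report = compute_metrics(cm)
    pos_idx = bundle.forest.class_names.index(positive_class)
    report.mae, report.rmse = mae_rmse((truth == positive_class).astype(float), proba[:, pos_idx])
    report.training_time_s = bundle.training_time_s
    return report


def save_model(bundle: ModelBundle, path: str) -> None:
    """Serialize a trained pipeline to versioned JSON."""
    if not bundle.forest.trees:
        raise ValueError("refusing to save an empty forest")
    doc = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "normalizer": bundle.normalizer.to_dict(),
        "lda": bundle.lda.to_dict() if bundle.lda is not None else None,
        "forest": bundle.forest.to_dict(),
        "config": bundle.config.to_dict(),
        "training_time_s": bundle.training_time_s,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str) -> ModelBundle:
    """Inverse of :func:`save_model`; load(save(b)) predicts bit-identically."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"model file is corrupt or truncated: {exc}") from exc
    version = doc.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r} (expected {BUNDLE_FORMAT_VERSION})")
    return ModelBundle(
        normalizer=NormalizationParams.from_dict(doc["normalizer"]),
        lda=LDAModel.from_dict(doc["lda"]) if doc["lda"] is not None else None,
        forest=Forest.from_dict(doc["forest"]),
        config=PipelineConfig(**doc["config"]),
        training_time_s=doc.get("training_time_s"),
    )
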