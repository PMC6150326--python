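"""RBF-SVM training with grid search, probability scores and class calls.

Features are z-score standardized inside the model using training data only
(an RBF kernel on mixed-scale feature groups requires it), hyperparameters
are chosen by 10-fold cross-validated AUC over a log2 grid, and posterior
probabilities come from Platt (sigmoid) calibration as implemented by the
underlying libsvm wrapper.  Class calls threshold the posterior at 0.5 by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .encoders import FeatureLayout

_MODEL_SCHEMA = "glypre.svm-model.v1"


@dataclass(frozen=True)
class CVSpec:
    """Fixed-hyperparameter cross-validation used inside selection loops."""

    k: int = 10
    seed: int = 0
    C: float = 1.0
    gamma: float | str = "scale"
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 folds")


@dataclass(frozen=True)
class SVMConfig:
    """Grid-search configuration (libsvm practical-guide default ranges)."""

    kernel: str = "rbf"
    C_grid: tuple[float, ...] = tuple(2.0 ** e for e in range(-5, 16, 2))
    gamma_grid: tuple[float, ...] = tuple(2.0 ** e for e in range(-15, 4, 2))
    cv_folds: int = 10
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("grids must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class TrainedModel:
    """A fitted scaler+SVC pipeline with its chosen hyperparameters."""

    pipeline: Pipeline
    C: float
    gamma: float | str
    kernel: str
    threshold: float
    layout: FeatureLayout | None = None
    schema: str = _MODEL_SCHEMA

    @property
    def n_features(self) -> int:
        return int(self.pipeline.named_steps["scale"].n_features_in_)


def make_svm_pipeline(C: float, gamma: float | str, kernel: str = "rbf",
                      probability: bool = False, seed: int = 0,
                      calibration_folds: int = 5) -> Pipeline:
    """Scaler + SVC; with ``probability`` the SVC is wrapped in sigmoid
    (Platt) calibration fitted on internal cross-validated decision values."""
    svc = SVC(C=C, gamma=gamma, kernel=kernel, random_state=seed)
    est = (
        CalibratedClassifierCV(svc, method="sigmoid", ensemble=False,
                               cv=calibration_folds)
        if probability else svc
    )
    return Pipeline([("scale", StandardScaler()), ("svc", est)])


def _calibration_folds(y: np.ndarray, wanted: int = 5) -> int:
    smallest = int(np.bincount(np.asarray(y, dtype=int)).min())
    if smallest < 2:
        raise ValueError(
            "probability calibration needs at least 2 samples per class")
    return min(wanted, smallest)


def make_folds(y: np.ndarray, cv: CVSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """One fixed stratified partition, reusable across candidate evaluations."""
    skf = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    return list(skf.split(np.zeros(len(y)), y))


def cross_val_auc(X: np.ndarray, y: np.ndarray, cv: CVSpec,
                  folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None
                  ) -> float:
    """Mean fold AUC of a fixed-hyperparameter SVM (decision-function scores)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = folds if folds is not None else make_folds(y, cv)
    aucs = []
    for train, test in folds:
        pipe = make_svm_pipeline(cv.C, cv.gamma, cv.kernel, seed=cv.seed)
        pipe.fit(X[train], y[train])
        scores = pipe.decision_function(X[test])
        aucs.append(roc_auc_score(y[test], scores))
    return float(np.mean(aucs))


def _validate_matrix(X: np.ndarray, layout: FeatureLayout | None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    bad = np.where(~np.isfinite(X))
    if bad[0].size:
        col = int(bad[1][0])
        name = layout.labels[col] if layout is not None else f"column {col}"
        raise ValueError(f"non-finite value in feature {name}")
    return X


def grid_search_train(X: np.ndarray, y: np.ndarray, cfg: SVMConfig,
                      layout: FeatureLayout | None = None) -> TrainedModel:
    """Pick (C, gamma) by mean CV AUC over the grid, then refit on all data.

    Ties keep the smaller C, then the smaller gamma (the grid is walked in
    ascending order and only strict improvements replace the incumbent).
    Deterministic given ``cfg.seed``.
    """
    X = _validate_matrix(X, layout)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    folds = make_folds(y, CVSpec(k=cfg.cv_folds, seed=cfg.seed))
    best_auc = -np.inf
    best: tuple[float, float] | None = None
    for C in sorted(cfg.C_grid):
        for gamma in sorted(cfg.gamma_grid):
            spec = CVSpec(k=cfg.cv_folds, seed=cfg.seed, C=C, gamma=gamma,
                          kernel=cfg.kernel)
            auc = cross_val_auc(X, y, spec, folds=folds)
            if auc > best_auc:
                best_auc = auc
                best = (C, gamma)
    assert best is not None
    C, gamma = best
    pipe = make_svm_pipeline(C, gamma, cfg.kernel, probability=True,
                             seed=cfg.seed,
                             calibration_folds=_calibration_folds(y))
    pipe.fit(X, y)
    return TrainedModel(pipe, C, gamma, cfg.kernel, cfg.threshold, layout)


def train_fixed(X: np.ndarray, y: np.ndarray, C: float = 1.0,
                gamma: float | str = "scale", kernel: str = "rbf",
                threshold: float = 0.5, seed: int = 0,
                layout: FeatureLayout | None = None) -> TrainedModel:
    """Fit the scaler+SVC pipeline at fixed hyperparameters (no grid search)."""
    X = _validate_matrix(X, layout)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    pipe = make_svm_pipeline(C, gamma, kernel, probability=True, seed=seed,
                             calibration_folds=_calibration_folds(y))
    pipe.fit(X, y)
    return TrainedModel(pipe, C, gamma, kernel, threshold, layout)


def _check_compatible(model: TrainedModel, X: np.ndarray,
                      layout: FeatureLayout | None) -> np.ndarray:
    X = _validate_matrix(X, layout or model.layout)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature count mismatch: model expects {model.n_features}, "
            f"got {X.shape[1]}"
        )
    if layout is not None and model.layout is not None:
        if layout.labels != model.layout.labels:
            raise ValueError("feature layout does not match the trained model")
    return X


def predict_scores(model: TrainedModel, X: np.ndarray,
                   layout: FeatureLayout | None = None) -> np.ndarray:
    """Posterior probability of the positive class, one score per row."""
    X = _check_compatible(model, X, layout)
    return model.pipeline.predict_proba(X)[:, 1]


def classify(model: TrainedModel, X: np.ndarray,
             layout: FeatureLayout | None = None) -> np.ndarray:
    """Binary call: positive iff the posterior score reaches the threshold."""
    return (predict_scores(model, X, layout) >= model.threshold).astype(int)


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump({"schema": _MODEL_SCHEMA, "model": model}, path)


def load_model(path: str | Path) -> TrainedModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # truncated / corrupt file
        raise ValueError(f"could not read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("schema") != _MODEL_SCHEMA:
        raise ValueError(
            f"model file {path} has schema {payload.get('schema') if isinstance(payload, dict) else None!r}; "
            f"this version reads {_MODEL_SCHEMA!r}"
        )
    return payload["model"]
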