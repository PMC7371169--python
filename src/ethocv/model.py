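"""Probabilistic multi-class RBF-SVM classifier stage.

A thin, contract-enforcing wrapper around :class:`sklearn.svm.SVC` with the
RBF kernel: one-versus-one multi-class decomposition with pairwise-coupled
class-probability estimates, feature standardization fitted on the training
rows only, and deterministic behaviour given (data, params, seed).
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .errors import FeatureMismatchError, ValidationError
from .features import FeatureDataset, Scaler, fit_scaler

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class HyperParams:
    """The two RBF-SVM hyperparameters: margin penalty C and kernel width gamma."""

    C: float
    gamma: float

    def __post_init__(self):
        if self.C <= 0 or self.gamma <= 0:
            raise ValidationError(
                f"C and gamma must be > 0, got C={self.C}, gamma={self.gamma}"
            )


@dataclass(frozen=True)
class GridSpec:
    """Log-spaced hyperparameter grid.

    Defaults enumerate 27 C values spanning 1e-5..1e9 crossed with 24 gamma
    values spanning 1e-9..1e3 — 648 points.
    """

    c_min: float = 1e-5
    c_max: float = 1e9
    c_count: int = 27
    gamma_min: float = 1e-9
    gamma_max: float = 1e3
    gamma_count: int = 24

    def __post_init__(self):
        if min(self.c_min, self.c_max, self.gamma_min, self.gamma_max) <= 0:
            raise ValidationError("grid endpoints must be positive")
        if self.c_count < 1 or self.gamma_count < 1:
            raise ValidationError("grid counts must be >= 1")

    def c_values(self) -> np.ndarray:
        return np.logspace(np.log10(self.c_min), np.log10(self.c_max),
                           self.c_count)

    def gamma_values(self) -> np.ndarray:
        return np.logspace(np.log10(self.gamma_min), np.log10(self.gamma_max),
                           self.gamma_count)

    def points(self) -> list[HyperParams]:
        """Cartesian product, C-major, ascending — the grid-search tie order."""
        return [HyperParams(float(c), float(g))
                for c in self.c_values() for g in self.gamma_values()]

    @classmethod
    def desk_scale(cls, c_count: int = 7, gamma_count: int = 6) -> "GridSpec":
        """Reduced grid over the same ranges, for laptop-scale runs."""
        return cls(c_count=c_count, gamma_count=gamma_count)


@dataclass
class TrainedModel:
    """Fitted classifier with its class list and standardization parameters."""

    svc: SVC
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    scaler: Scaler
    params: HyperParams
    seed: int


def fit(train: FeatureDataset, params: HyperParams, seed: int = 0,
        ) -> TrainedModel:
    """Train the one-versus-one RBF-SVM with probability estimation.

    Features are standardized with parameters fitted on ``train`` only; the
    internal probability-calibration cross-validation is seeded for
    reproducibility.
    """
    classes = train.classes
    if len(classes) < 2:
        raise ValidationError(
            f"training data must contain >= 2 classes, got {classes}"
        )
    scaler = fit_scaler(train.X)
    with warnings.catch_warnings():
        # pairwise-coupled Platt probabilities are the intended construction
        warnings.filterwarnings("ignore", message=".*probability.*",
                                category=FutureWarning)
        svc = SVC(kernel="rbf", C=params.C, gamma=params.gamma,
                  probability=True, random_state=seed)
        svc.fit(scaler.transform(train.X), train.y.astype(str))
    fitted = tuple(svc.classes_.tolist())
    assert fitted == classes, (fitted, classes)  # SVC sorts labels
    return TrainedModel(svc, classes, train.feature_names, scaler,
                        params, seed)


def predict_proba(model: TrainedModel, test: FeatureDataset) -> np.ndarray:
    """(n, K) class-probability matrix, columns ordered as ``model.classes``.

    Rows sum to 1 within 1e-6. Classes absent from training have no column.
    """
    if test.feature_names != model.feature_names:
        raise FeatureMismatchError(
            "test feature names do not match the training features"
        )
    if test.n == 0:
        return np.empty((0, len(model.classes)))
    proba = model.svc.predict_proba(model.scaler.transform(test.X))
    return proba


def predict_from_proba(proba: np.ndarray, classes) -> np.ndarray:
    """Row-wise argmax labels; ties break toward the earlier sorted class."""
    classes = np.asarray(classes, dtype=object)
    if proba.shape[0] == 0:
        return np.empty(0, dtype=object)
    return classes[np.argmax(proba, axis=1)]


def predict(model: TrainedModel, test: FeatureDataset) -> np.ndarray:
    return predict_from_proba(predict_proba(model, test), model.classes)


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model to one file (versioned pickle)."""
    payload = {"format_version": MODEL_FORMAT_VERSION, "model": model}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> TrainedModel:
    with open(Path(path), "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported model format {payload.get('format_version')!r}"
        )
    return payload["model"]
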