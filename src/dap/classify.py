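"""Pathology classification from compact DAP parameters.

A fitted instance is summarized by the descriptor ``Phi = [b_s, b_A]``
(shape and appearance PCA coefficients).  A further PCA over training
descriptors spans a feature space; the reduced coordinates ``b_Phi`` feed
an AdaBoost ensemble of shallow decision trees that predicts a pathology
label or stenosis grade (normal / moderate / severe).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier

from .appearance import Shape, vectorize
from .model import DAPModel
from .priors import PCAModel, fit_pca
from .pyramids import ImagePyramid

__all__ = [
    "InstanceDescriptor",
    "FeatureSpace",
    "GradeClassifier",
    "assemble_descriptor",
    "fit_feature_space",
    "train_classifier",
    "predict_label",
    "accuracy",
    "grading_mae",
    "grading_rmse",
]


@dataclass
class InstanceDescriptor:
    """Phi = [b_s, b_A] for one fitted instance."""

    phi: np.ndarray
    n_shape: int  # length of the b_s block

    @property
    def b_s(self) -> np.ndarray:
        return self.phi[: self.n_shape]

    @property
    def b_a(self) -> np.ndarray:
        return self.phi[self.n_shape :]


class FeatureSpace(PCAModel):
    """PCA space over training descriptors; b_Phi = P^T (Phi - mean)."""


def assemble_descriptor(
    model: DAPModel, pyramid: ImagePyramid, s: Shape
) -> InstanceDescriptor:
    """Extract the AP at the fitted shape, project both blocks, concatenate."""
    if s.n_points != model.geometry.n_landmarks:
        raise ValueError("shape does not match model geometry")
    b_s = model.shape_model.project_shape(s)
    a = model.appearance_model.normalize(vectorize(model.geometry.extract(pyramid, s)))
    b_a = model.appearance_model.project(a)
    return InstanceDescriptor(phi=np.concatenate([b_s, b_a]), n_shape=b_s.size)


def fit_feature_space(
    descriptors: list[InstanceDescriptor] | np.ndarray,
    variance_fraction: float = 0.95,
) -> FeatureSpace:
    X = np.asarray(
        [d.phi if isinstance(d, InstanceDescriptor) else d for d in descriptors],
        dtype=float,
    )
    mean, P, eig = fit_pca(X, variance_fraction)
    return FeatureSpace(mean=mean, components=P, eigenvalues=eig)


@dataclass
class GradeClassifier:
    """AdaBoost (SAMME) over depth-limited trees in the b_Phi space."""

    booster: AdaBoostClassifier
    classes: np.ndarray

    def scores(self, b_phi: np.ndarray) -> np.ndarray:
        b_phi = np.atleast_2d(b_phi)
        return self.booster.predict_proba(b_phi)

    def predict(self, b_phi: np.ndarray) -> np.ndarray:
        b_phi = np.atleast_2d(b_phi)
        return self.booster.predict(b_phi)


def train_classifier(
    b_phi: np.ndarray,
    labels: np.ndarray,
    cycles: int = 100,
    max_depth: int = 2,
    seed: int = 0,
) -> GradeClassifier:
    """Boost ``cycles`` shallow trees on the compact features.

    Multiclass grading uses SAMME boosting; deterministic given the seed.
    """
    b_phi = np.atleast_2d(np.asarray(b_phi, dtype=float))
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    booster = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=max_depth, random_state=seed),
        n_estimators=cycles,
        random_state=seed,
    )
    booster.fit(b_phi, labels)
    return GradeClassifier(booster=booster, classes=booster.classes_)


def predict_label(
    classifier: GradeClassifier,
    feature_space: FeatureSpace,
    descriptor: InstanceDescriptor | np.ndarray,
):
    """argmax-probability label for one descriptor; also returns the scores."""
    phi = descriptor.phi if isinstance(descriptor, InstanceDescriptor) else descriptor
    b = feature_space.project(np.asarray(phi, dtype=float))
    scores = classifier.scores(b)[0]
    label = classifier.classes[int(np.argmax(scores))]
    return label, scores


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """(tp + tn) / (tp + tn + fp + fn) — the fraction of exact agreements."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    return float(np.mean(pred == truth))


def grading_mae(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute error on integer-coded grades {0, 1, 2}."""
    return float(np.mean(np.abs(np.asarray(pred, float) - np.asarray(truth, float))))


def grading_rmse(pred: np.ndarray, truth: np.ndarray) -> float:
    """Root mean squared error on integer-coded grades."""
    d = np.asarray(pred, float) - np.asarray(truth, float)
    return float(np.sqrt(np.mean(d**2)))
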