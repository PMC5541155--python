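"""PCA priors over shape and appearance.

The shape prior is a point-distribution model: landmark configurations are
translation-aligned to the mean centroid and decomposed by PCA into a mean
``s_bar`` plus ``t`` orthonormal modes with eigenvalue variances
``lambda_1 >= ... >= lambda_t``.  Shape plausibility is the Mahalanobis
log-density ``-1/2 * sum_j b_j**2 / lambda_j`` in mode coordinates.

The appearance prior is a PCA over per-sample z-score-normalized appearance
pyramid vectors.  Both models retain the smallest number of components whose
cumulative eigenvalue share reaches a variance fraction (default 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .appearance import Shape

__all__ = [
    "PCAModel",
    "AppearanceModel",
    "ShapeModel",
    "normalize_sample",
    "fit_pca",
    "fit_appearance_model",
    "fit_shape_model",
    "shape_log_density",
]

_VAR_FLOOR = 1e-12


def normalize_sample(a: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance normalization of one appearance vector.

    A (near-)constant vector maps to all zeros rather than dividing by a
    vanishing standard deviation.
    """
    a = np.asarray(a, dtype=float)
    if a.size < 2:
        raise ValueError("sample must have length >= 2")
    out = a - a.mean()
    sd = out.std()
    if sd < np.sqrt(_VAR_FLOOR):
        return np.zeros_like(out)
    return out / sd


def fit_pca(
    samples: np.ndarray | list[np.ndarray], variance_fraction: float = 0.95
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of row-vector samples; returns (mean, eigenvectors, eigenvalues).

    Eigenvalues are sample-covariance eigenvalues (divisor M-1), descending;
    the retained count is the smallest whose cumulative share reaches
    ``variance_fraction``.  Computed by economy SVD of the centered data so
    the appearance case (dimension >> sample count) never forms the full
    covariance.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError("variance_fraction must lie in (0, 1]")
    M = X.shape[0]
    mean = X.mean(axis=0)
    Xc = X - mean
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = sv**2 / (M - 1)
    keep = eig > _VAR_FLOOR * max(1.0, eig[0] if eig.size else 1.0)
    eig = eig[keep]
    Vt = Vt[keep]
    if eig.size == 0:
        return mean, np.zeros((X.shape[1], 0)), np.zeros(0)
    share = np.cumsum(eig) / eig.sum()
    q = int(np.searchsorted(share, variance_fraction - 1e-12) + 1)
    q = min(q, eig.size)
    return mean, Vt[:q].T.copy(), eig[:q].copy()


@dataclass
class PCAModel:
    """Mean + orthonormal component matrix + eigenvalue variances."""

    mean: np.ndarray
    components: np.ndarray  # (D, q), orthonormal columns
    eigenvalues: np.ndarray  # (q,), descending

    @property
    def dim(self) -> int:
        return self.mean.size

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def project(self, sample: np.ndarray) -> np.ndarray:
        """b = P^T (sample - mean)."""
        sample = np.asarray(sample, dtype=float)
        if sample.size != self.dim:
            raise ValueError(
                f"sample length {sample.size} != model dimension {self.dim}"
            )
        return self.components.T @ (sample - self.mean)

    def reconstruct(self, b: np.ndarray) -> np.ndarray:
        """mean + P b."""
        b = np.asarray(b, dtype=float)
        if b.size != self.n_components:
            raise ValueError("coefficient length mismatch")
        return self.mean + self.components @ b


@dataclass
class AppearanceModel(PCAModel):
    """PCA prior over normalized, vectorized appearance pyramids."""

    normalization: str = "zscore"  # "zscore" | "none"

    def normalize(self, a: np.ndarray) -> np.ndarray:
        if self.normalization == "zscore":
            return normalize_sample(a)
        return np.asarray(a, dtype=float)


@dataclass
class ShapeModel(PCAModel):
    """Point-distribution model in translation-aligned image coordinates."""

    mean_centroid: np.ndarray = field(default_factory=lambda: np.zeros(2))

    @property
    def n_landmarks(self) -> int:
        return self.dim // 2

    def align(self, s: Shape) -> np.ndarray:
        """Translate ``s`` so its centroid matches the training mean centroid."""
        pts = s.points - s.centroid() + self.mean_centroid
        return pts.reshape(-1)

    def project_shape(self, s: Shape, align: bool = True) -> np.ndarray:
        v = self.align(s) if align else s.as_vector()
        return self.project(v)

    def mean_shape(self) -> Shape:
        return Shape.from_vector(self.mean)


def fit_appearance_model(
    samples: list[np.ndarray],
    variance_fraction: float = 0.95,
    normalization: str = "zscore",
) -> AppearanceModel:
    """Normalize each appearance vector, then PCA."""
    if normalization not in ("zscore", "none"):
        raise ValueError(f"unknown normalization rule {normalization!r}")
    if normalization == "zscore":
        samples = [normalize_sample(a) for a in samples]
    mean, P, eig = fit_pca(np.asarray(samples, dtype=float), variance_fraction)
    return AppearanceModel(
        mean=mean, components=P, eigenvalues=eig, normalization=normalization
    )


def fit_shape_model(
    shapes: list[Shape], variance_fraction: float = 0.95
) -> ShapeModel:
    """Translation-align shapes to the mean centroid, then PCA."""
    cents = np.array([s.centroid() for s in shapes])
    mean_centroid = cents.mean(axis=0)
    aligned = np.array(
        [(s.points - c + mean_centroid).reshape(-1) for s, c in zip(shapes, cents)]
    )
    mean, P, eig = fit_pca(aligned, variance_fraction)
    return ShapeModel(
        mean=mean, components=P, eigenvalues=eig, mean_centroid=mean_centroid
    )


def shape_log_density(model: ShapeModel, s: Shape, align: bool = True) -> float:
    """Log of the unnormalized shape density: ``-1/2 sum_j b_j^2 / lambda_j``."""
    b = model.project_shape(s, align=align)
    return float(-0.5 * np.sum(b**2 / model.eigenvalues))
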