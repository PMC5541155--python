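"""Implicit DAP fitting: supervised-descent cascade of ridge regressors.

Landmark detection is cast as regression from appearance features observed
at the current shape estimate to a shape increment.  Each cascade stage is
a linear map ``delta_s = R h(A(s)) + b`` trained in closed form by ridge
regression (the bias column is excluded from the L2 penalty by centering);
training shapes for stage i+1 are produced by applying stage i.  The
feature function ``h`` is either per-patch HOG descriptors or raw
intensities of the appearance pyramid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .appearance import Shape, vectorize
from .model import DAPModel, ModelGeometry
from .priors import normalize_sample
from .pyramids import ImagePyramid

__all__ = [
    "SDMStage",
    "SDMCascade",
    "hog_descriptor",
    "sdm_features",
    "solve_ridge_stage",
    "train_sdm",
    "apply_sdm",
]


def hog_descriptor(patch: np.ndarray, cells: int = 4, bins: int = 9) -> np.ndarray:
    """Histogram of oriented gradients of one patch, single-block L2-hys.

    Unsigned orientations in [0, pi) are hard-assigned to ``bins`` equal
    bins (bin 0 holds horizontal gradients, i.e. vertical edges) and
    magnitude-weighted per cell; the ``cells**2 * bins`` vector is L2
    normalized, clipped at 0.2 and renormalized.  A gradient-free patch
    yields the zero vector.
    """
    patch = np.asarray(patch, dtype=float)
    side = patch.shape[0]
    if patch.shape[0] != patch.shape[1]:
        raise ValueError("patch must be square")
    if side % cells != 0:
        raise ValueError(f"patch side {side} not divisible into {cells} cells")
    gr, gc = np.gradient(patch)
    mag = np.hypot(gr, gc)
    theta = np.mod(np.arctan2(gr, gc), np.pi)
    bin_idx = np.minimum((theta / np.pi * bins).astype(int), bins - 1)
    cs = side // cells
    hist = np.zeros((cells, cells, bins))
    for i in range(cells):
        for j in range(cells):
            b = bin_idx[i * cs : (i + 1) * cs, j * cs : (j + 1) * cs].ravel()
            m = mag[i * cs : (i + 1) * cs, j * cs : (j + 1) * cs].ravel()
            hist[i, j] = np.bincount(b, weights=m, minlength=bins)
    v = hist.reshape(-1)
    nrm = np.linalg.norm(v)
    if nrm < 1e-12:
        return np.zeros_like(v)
    v = np.minimum(v / nrm, 0.2)
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 1e-12 else v


@dataclass
class SDMStage:
    R: np.ndarray  # (2N, D)
    b: np.ndarray  # (2N,)
    feature: str


@dataclass
class SDMCascade:
    """Ordered regression stages plus the initial-shape rule."""

    stages: list[SDMStage]
    s0: np.ndarray  # mean training shape vector (2N,)
    feature: str
    hog_cells: int
    hog_bins: int
    ridge_weight: float | str
    training_errors: list[float] = field(default_factory=list)

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def initial_shape(self) -> Shape:
        return Shape.from_vector(self.s0)


def sdm_features(
    geom: ModelGeometry,
    pyramid: ImagePyramid,
    s: Shape,
    feature: str = "hog",
    cells: int = 4,
    bins: int = 9,
) -> np.ndarray:
    """Feature vector h(A(s)) over the full trimmed appearance pyramid.

    HOG patches are cropped to the largest cell-divisible side (default
    p=17 -> 16).  Intensity features are the vectorized AP, z-scored.
    """
    ap = geom.extract(pyramid, s)
    if feature == "intensity":
        return normalize_sample(vectorize(ap))
    if feature != "hog":
        raise ValueError(f"unknown feature id {feature!r}")
    side = (geom.p // cells) * cells
    return np.concatenate(
        [hog_descriptor(pt.pixels[:side, :side], cells, bins) for pt in ap.patches]
    )


def solve_ridge_stage(
    X: np.ndarray, Y: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form multi-output ridge with unpenalized bias.

    Centers features and targets, solves
    ``argmin ||Yc - Xc W||^2 + lam ||W||^2`` via the primal or dual normal
    equations (whichever Gram is smaller), and recovers the bias.  With
    ``lam == 0`` the minimum-norm least-squares solution is used.
    Returns ``(R, b)`` with ``R = W.T``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    M, D = X.shape
    xbar = X.mean(axis=0)
    ybar = Y.mean(axis=0)
    Xc = X - xbar
    Yc = Y - ybar
    if lam == 0.0:
        W, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    elif D <= M:
        W = np.linalg.solve(Xc.T @ Xc + lam * np.eye(D), Xc.T @ Yc)
    else:
        W = Xc.T @ np.linalg.solve(Xc @ Xc.T + lam * np.eye(M), Yc)
    b = ybar - xbar @ W
    return W.T, b


def _auto_lambda(Xc: np.ndarray) -> float:
    # scale-aware one-value rule: 0.01 * trace(Gram) / feature dim
    return 0.01 * float(np.sum(Xc**2)) / Xc.shape[1]


def train_sdm(
    images: list[np.ndarray],
    shapes: list[Shape],
    model: DAPModel,
    stages: int = 4,
    lam: float | str = "auto",
    feature: str = "hog",
    perturbations: int = 0,
    seed: int = 0,
    hog_cells: int = 4,
    hog_bins: int = 9,
) -> SDMCascade:
    """Train the cascade and attach it to ``model``.

    Stage 0 starts every sample from the mean training shape (the "average
    shape at the average location"), optionally augmented with
    ``perturbations`` random translated/scaled initializations per image.
    Each stage solves the ridge problem on (features, shape residuals) and
    produces the next stage's shapes by applying itself.
    """
    if len(images) != len(shapes) or len(images) < 1:
        raise ValueError("need matched, non-empty images and shapes")
    if stages < 1:
        raise ValueError("stages must be >= 1")
    geom = model.geometry
    pyramids = [geom.build_pyramid(im) for im in images]
    s_true = [s.as_vector() for s in shapes]
    s0 = np.mean(s_true, axis=0)

    idx = list(range(len(images)))
    current = [s0.copy() for _ in idx]
    if perturbations > 0:
        rng = np.random.default_rng(seed)
        for k in range(len(images)):
            for _ in range(perturbations):
                t = rng.normal(0.0, 3.0, size=2)
                sc = float(np.exp(rng.normal(0.0, 0.05)))
                pts = Shape.from_vector(s0).points
                c = pts.mean(axis=0)
                pts = (pts - c) * sc + c + t
                idx.append(k)
                current.append(pts.reshape(-1))

    def feats(k: int, sv: np.ndarray) -> np.ndarray:
        return sdm_features(
            geom, pyramids[k], Shape.from_vector(sv), feature, hog_cells, hog_bins
        )

    cascade = SDMCascade(
        stages=[],
        s0=s0,
        feature=feature,
        hog_cells=hog_cells,
        hog_bins=hog_bins,
        ridge_weight=lam,
    )
    for _ in range(stages):
        X = np.stack([feats(k, sv) for k, sv in zip(idx, current)])
        Y = np.stack([s_true[k] - sv for k, sv in zip(idx, current)])
        lam_i = _auto_lambda(X - X.mean(axis=0)) if lam == "auto" else float(lam)
        R, b = solve_ridge_stage(X, Y, lam_i)
        cascade.stages.append(SDMStage(R=R, b=b, feature=feature))
        current = [sv + R @ x + b for sv, x in zip(current, X)]
        err = float(
            np.mean(
                [
                    np.mean(
                        np.linalg.norm(
                            (sv - s_true[k]).reshape(-1, 2), axis=1
                        )
                    )
                    for k, sv in zip(idx, current)
                ]
            )
        )
        cascade.training_errors.append(err)
    model.cascade = cascade
    return cascade


def apply_sdm(
    pyramid: ImagePyramid,
    model: DAPModel,
    s_init: Shape | None = None,
) -> Shape:
    """Run every cascade stage in order from ``s_init`` (default: mean shape)."""
    cascade = model.cascade
    if cascade is None:
        raise ValueError("model has no trained SDM cascade")
    geom = model.geometry
    sv = (s_init.as_vector() if s_init is not None else cascade.s0).copy()
    if sv.size != 2 * geom.n_landmarks:
        raise ValueError("initial shape does not match model geometry")
    for stage in cascade.stages:
        f = sdm_features(
            geom,
            pyramid,
            Shape.from_vector(sv),
            cascade.feature,
            cascade.hog_cells,
            cascade.hog_bins,
        )
        if stage.R.shape[1] != f.size:
            raise ValueError("feature dimension does not match cascade geometry")
        sv = sv + stage.R @ f + stage.b
    return Shape.from_vector(sv)
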