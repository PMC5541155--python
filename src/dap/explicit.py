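"""Explicit DAP fitting: subspace Lucas-Kanade search + closed-form MAP shape.

Each retained patch is aligned against the mean-appearance template by
inverse-gradient-descent LK, but in the *orthogonal complement* of the
appearance eigenspace, so learned population variation is not mistaken for
misalignment.  Every patch yields a landmark prediction ``x_hat`` with a
confidence ``sigma2`` (mean squared projected residual).  The multi-scale
predictions and the shape prior combine into a quadratic energy

    E(s) = 1/2 sum_j b_j^2/lambda_j
         + sum_n sum_{l in K_n} ||x_n - x_hat_{n,l}||^2 / (2 sigma2_{n,l})

whose unique minimizer has the closed form
``s = (P L^-1 P^T + sum_l S_l^-1)^-1 (P L^-1 P^T s_bar + sum_l S_l^-1 s_hat_l)``.
Fitting alternates the per-patch searches with this MAP shape until the
landmarks stop moving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .appearance import Shape, block_slices, extract_patch, vectorize
from .model import DAPModel
from .priors import AppearanceModel, PCAModel, ShapeModel
from .pyramids import ImagePyramid

__all__ = [
    "LandmarkPrediction",
    "ExplicitFitState",
    "SearchContext",
    "ExplicitFitter",
    "project_orthogonal",
    "lk_search",
    "map_shape",
    "map_energy",
    "fit_explicit",
]

_SIGMA_FLOOR = 1e-6


def project_orthogonal(model: PCAModel, a: np.ndarray) -> np.ndarray:
    """Project onto the orthogonal complement of the eigenspace:
    ``a - P (P^T a)``."""
    a = np.asarray(a, dtype=float)
    if a.size != model.dim:
        raise ValueError(f"vector length {a.size} != model dimension {model.dim}")
    P = model.components
    return a - P @ (P.T @ a)


@dataclass
class LandmarkPrediction:
    """A single patch's landmark estimate in the level-1 frame."""

    x: np.ndarray  # (2,) (row, col)
    sigma2: float
    converged: bool
    iterations: int


@dataclass
class ExplicitFitState:
    shape: Shape
    iteration: int
    energies: list[float] = field(default_factory=list)
    predictions: dict = field(default_factory=dict)


@dataclass
class SearchContext:
    """Per-outer-iteration frozen quantities for the blockwise projection.

    The global projector of the subspace-LK objective acts on the full
    vectorized AP; its coefficients are computed once from the appearance
    observed at the current shape and held fixed while each patch's LK
    iterations move the landmark.
    """

    mu: float
    sd: float
    correction: np.ndarray  # P (P^T (a - mean)), full-length


def _patch_gradient(patch: np.ndarray) -> np.ndarray:
    """(p*p, 2) spatial gradient columns (d/drow, d/dcol), central differences."""
    gr, gc = np.gradient(patch)
    return np.stack([gr.reshape(-1), gc.reshape(-1)], axis=1)


class ExplicitFitter:
    """Precomputed templates, projectors and Jacobian pseudo-inverses."""

    def __init__(self, model: DAPModel, svd_cutoff: float = 1e-8):
        self.model = model
        geom = model.geometry
        am = model.appearance_model
        self.slices = block_slices(geom.K, geom.p)
        self.mean_vec = am.mean
        self.mean_perp = project_orthogonal(am, am.mean)
        p = geom.p
        self._ctx_tpl: dict = {}
        self._solo_tpl: dict = {}
        for pair, sl in self.slices.items():
            # per-block orthonormal basis of the appearance eigenspace rows:
            # the block's learned variation directions
            B = am.components[sl, :]
            Q = _orthonormal_columns(B, svd_cutoff)
            # steepest-descent images: spatial gradient of the mean template
            # block with the learned variation projected out
            T = self.mean_vec[sl]
            G = _patch_gradient(T.reshape(p, p))
            Gp = G - Q @ (Q.T @ G)
            Gpinv = np.linalg.pinv(Gp, rcond=svd_cutoff)
            self._ctx_tpl[pair] = (T, Q, Gpinv)
            Ts = _zscore(T)
            Gs = _patch_gradient(Ts.reshape(p, p))
            Gsp = Gs - Q @ (Q.T @ Gs)
            self._solo_tpl[pair] = (Ts, Q, np.linalg.pinv(Gsp, rcond=svd_cutoff))

    def make_context(self, pyramid: ImagePyramid, s: Shape) -> SearchContext:
        geom = self.model.geometry
        am = self.model.appearance_model
        a_raw = vectorize(geom.extract(pyramid, s))
        if am.normalization == "zscore":
            mu = float(a_raw.mean())
            sd = float(a_raw.std())
            if sd < 1e-9:
                sd = 1.0
            a = (a_raw - mu) / sd
        else:
            mu, sd = 0.0, 1.0
            a = a_raw
        d = a - am.mean
        corr = am.components @ (am.components.T @ d)
        return SearchContext(mu=mu, sd=sd, correction=corr)

    def search(
        self,
        pyramid: ImagePyramid,
        x0: np.ndarray,
        n: int,
        l: int,
        max_iter: int = 30,
        tol: float = 1e-2,
        context: SearchContext | None = None,
    ) -> LandmarkPrediction:
        geom = self.model.geometry
        p = geom.p
        sl = self.slices[(n, l)]
        scale = 2.0 ** (l - 1)
        x0 = np.asarray(x0, dtype=float)
        x = x0.copy()
        converged = False
        wandered = False
        it = 0
        r = np.zeros(p * p)
        a_blk = np.zeros(p * p)
        step_cap = p / 4.0  # per-iteration trust region, level-l pixels
        wander_cap = p / 2.0  # beyond this the patch left its origin
        for it in range(1, max_iter + 1):
            obs = extract_patch(pyramid, x, l, p).pixels.reshape(-1)
            if context is not None:
                T, Q, Gpinv = self._ctx_tpl[(n, l)]
                a_blk = (obs - context.mu) / context.sd
                r = a_blk - T - context.correction[sl]
            else:
                T, Q, Gpinv = self._solo_tpl[(n, l)]
                a_blk = _zscore(obs)
                r = a_blk - T
            if it == 1 and np.var(a_blk) < 1e-8 * max(np.var(T), 1e-12):
                # textureless observation: no signal to align to
                converged = True
                wandered = True  # report maximal uncertainty
                break
            r = r - Q @ (Q.T @ r)
            delta = -(Gpinv @ r)  # level-l pixels
            nrm = np.linalg.norm(delta)
            if nrm > step_cap:
                delta *= step_cap / nrm
            x = x + scale * delta
            drift = (x - x0) / scale
            dn = np.linalg.norm(drift)
            if dn > wander_cap:
                x = x0 + scale * drift * (wander_cap / dn)
                wandered = True
            if np.linalg.norm(scale * delta) < tol:
                converged = True
                break
        # confidence: mean squared projected residual, in the normalized
        # intensity units of the observation; a search that ran off its
        # origin patch is maximally unconfident
        cap = max(float(np.var(a_blk)), float(np.var(T)), _SIGMA_FLOOR)
        sigma2 = cap if wandered else float(np.mean(r**2))
        sigma2 = min(max(sigma2, _SIGMA_FLOOR), cap)
        return LandmarkPrediction(x=x, sigma2=sigma2, converged=converged, iterations=it)

    def search_all(
        self,
        pyramid: ImagePyramid,
        s: Shape,
        max_iter: int = 30,
        tol: float = 1e-2,
    ) -> dict[tuple[int, int], LandmarkPrediction]:
        ctx = self.make_context(pyramid, s)
        return {
            (n, l): self.search(pyramid, s.points[n], n, l, max_iter, tol, ctx)
            for n, l in self.model.geometry.K.index_pairs()
        }


def _zscore(v: np.ndarray) -> np.ndarray:
    out = v - v.mean()
    sd = out.std()
    return out / sd if sd > 1e-9 else out


def _orthonormal_columns(B: np.ndarray, cutoff: float) -> np.ndarray:
    if B.size == 0:
        return np.zeros((B.shape[0], 0))
    U, sv, _ = np.linalg.svd(B, full_matrices=False)
    rank = int(np.sum(sv > cutoff * (sv[0] if sv.size else 1.0)))
    return U[:, :rank]


def lk_search(
    pyramid: ImagePyramid,
    model: DAPModel,
    x0: np.ndarray,
    n: int,
    l: int,
    max_iter: int = 30,
    tol: float = 1e-2,
    context: SearchContext | None = None,
    fitter: ExplicitFitter | None = None,
) -> LandmarkPrediction:
    """Subspace-LK search for landmark ``n`` at level ``l`` from ``x0``.

    Without a :class:`SearchContext` the projection falls back to the
    per-block orthonormalized complement (a true projector on the patch
    subspace); within :func:`fit_explicit` the context carries the frozen
    global projection of the full AP.
    """
    if fitter is None:
        fitter = ExplicitFitter(model)
    return fitter.search(pyramid, x0, n, l, max_iter, tol, context)


def _prior_matrices(shape_model: ShapeModel | None):
    if shape_model is None or shape_model.n_components == 0:
        return None, None
    P = shape_model.components
    Li = np.diag(1.0 / shape_model.eigenvalues)
    A = P @ Li @ P.T
    return A, A @ shape_model.mean


def map_shape(
    shape_model: ShapeModel | None,
    predictions: dict[tuple[int, int], LandmarkPrediction],
    n_landmarks: int | None = None,
) -> Shape:
    """Closed-form MAP fusion of multi-scale predictions with the shape prior.

    Solves the normal equations of the quadratic energy; trimmed (n, l)
    pairs simply contribute no observation weight.  With an empty prior the
    result is the per-landmark inverse-variance weighted mean.
    """
    if n_landmarks is None:
        if shape_model is None:
            n_landmarks = max(n for n, _ in predictions) + 1
        else:
            n_landmarks = shape_model.n_landmarks
    dim = 2 * n_landmarks
    A = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    Ap, bp = _prior_matrices(shape_model)
    if Ap is not None:
        A += Ap
        rhs += bp
    diag = np.zeros(dim)
    for (n, _l), pred in predictions.items():
        w = 1.0 / pred.sigma2
        diag[2 * n : 2 * n + 2] += w
        rhs[2 * n : 2 * n + 2] += w * pred.x
    if np.any(diag <= 0.0) and Ap is None:
        raise ValueError("every landmark needs at least one prediction")
    A[np.arange(dim), np.arange(dim)] += diag
    return Shape.from_vector(np.linalg.solve(A, rhs))


def map_energy(
    shape_model: ShapeModel | None,
    predictions: dict[tuple[int, int], LandmarkPrediction],
    s: Shape,
) -> float:
    """The quadratic energy E(s) the MAP shape minimizes."""
    e = 0.0
    if shape_model is not None and shape_model.n_components > 0:
        b = shape_model.components.T @ (s.as_vector() - shape_model.mean)
        e += 0.5 * float(np.sum(b**2 / shape_model.eigenvalues))
    for (n, _l), pred in predictions.items():
        e += float(np.sum((s.points[n] - pred.x) ** 2)) / (2.0 * pred.sigma2)
    return e


def fit_explicit(
    pyramid: ImagePyramid,
    model: DAPModel,
    s_init: Shape,
    outer_iters: int = 10,
    max_iter: int = 30,
    tol: float = 1e-2,
    motion_tol: float = 0.05,
) -> tuple[Shape, ExplicitFitState]:
    """Alternate LK searches at all retained patches with the MAP shape.

    Stops after ``outer_iters`` outer iterations or once the mean landmark
    motion drops below ``motion_tol`` pixels.
    """
    fitter = ExplicitFitter(model)
    state = ExplicitFitState(shape=s_init, iteration=0)
    s = s_init
    for i in range(outer_iters):
        preds = fitter.search_all(pyramid, s, max_iter=max_iter, tol=tol)
        s_new = map_shape(model.shape_model, preds)
        state.energies.append(map_energy(model.shape_model, preds, s_new))
        state.predictions = preds
        state.iteration = i + 1
        motion = float(np.mean(np.linalg.norm(s_new.points - s.points, axis=1)))
        s = s_new
        state.shape = s
        if motion < motion_tol:
            break
    return s, state
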