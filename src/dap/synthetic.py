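"""Synthetic disc/canal phantom populations for end-to-end testing.

Emulates the statistical structure a DAP assumes in an axial disc-level
image: a disc-like outer contour and a canal-like inner contour sharing a
fixed landmark budget, deformed by a known linear shape model (mean +
orthonormal smooth modes with Gaussian coefficients), rendered with smooth
region intensities, band-limited texture and i.i.d. sensor noise.  Mode 1
is a canal-narrowing mode; thresholding its coefficient yields a 3-grade
stenosis-like label, so grading is learnable from shape parameters and
texture intensity co-varies with the grade.

Everything derives from one explicit seed; per-instance noise uses
counter-indexed substreams, so identical specs give identical datasets.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .appearance import Shape
from .priors import ShapeModel

__all__ = [
    "GRADE_NAMES",
    "PhantomSpec",
    "SyntheticDataset",
    "make_generating_model",
    "render_instance",
    "generate_dataset",
]

GRADE_NAMES = ("normal", "moderate", "severe")


@dataclass
class PhantomSpec:
    """Generating conditions of a phantom population."""

    n_landmarks: int = 37
    image_size: tuple[int, int] = (128, 128)
    n_modes: int = 3
    mode_std: tuple[float, ...] | None = None  # default scales with image size
    texture_amplitude: float = 0.04
    texture_smoothness: float = 3.0
    noise_std: float = 0.02
    grade_thresholds: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_landmarks < 8:
            raise ValueError("need at least 8 landmarks for the two outlines")
        if self.n_modes < 1:
            raise ValueError("need at least one shape mode")
        if self.mode_std is None:
            # deformation amplitude proportional to anatomy (image) size
            scale = self.image_size[0] / 128.0
            base = (10.0, 6.0, 4.0)
            self.mode_std = tuple(
                scale * base[min(j, 2)] / 2 ** max(0, j - 2)
                for j in range(self.n_modes)
            )
        if len(self.mode_std) < self.n_modes:
            raise ValueError("mode_std must cover n_modes")
        if self.grade_thresholds is None:
            # tertile cuts of N(0, sigma_1^2): +/- 0.43073 sigma
            t = 0.4307272992954576 * self.mode_std[0]
            self.grade_thresholds = (-t, t)

    @property
    def n_inner(self) -> int:
        return max(6, self.n_landmarks // 3)

    @property
    def n_outer(self) -> int:
        return self.n_landmarks - self.n_inner


@dataclass
class RendererParams:
    outer_center: np.ndarray
    inner_center: np.ndarray
    n_outer: int
    n_inner: int
    background: float = 0.70
    disc_intensity: float = 0.40
    canal_intensity: float = 0.88
    grade_intensity_gain: float = 0.08
    edge_smoothing: float = 0.8


def _ellipse_points(center, radii, n, phase=0.0) -> np.ndarray:
    th = 2.0 * np.pi * np.arange(n) / n + phase
    return np.stack(
        [center[0] + radii[0] * np.sin(th), center[1] + radii[1] * np.cos(th)], axis=1
    )


def make_generating_model(spec: PhantomSpec) -> tuple[ShapeModel, RendererParams]:
    """Mean two-outline contour plus orthonormal smooth deformation modes.

    Mode 1 moves the inner (canal) contour radially inward for positive
    coefficients; further modes are anisotropic scalings, bendings and
    low-frequency radial ripples of the outer contour, Gram-Schmidt
    orthonormalized while preserving mode 1's direction.
    """
    rows, cols = spec.image_size
    oc = np.array([rows / 2.0, cols / 2.0])
    ic = oc + np.array([0.14 * rows, 0.0])
    o_radii = (0.33 * rows, 0.28 * cols)
    i_radii = (0.10 * rows, 0.085 * cols)
    outer = _ellipse_points(oc, o_radii, spec.n_outer)
    inner = _ellipse_points(ic, i_radii, spec.n_inner)
    mean_pts = np.concatenate([outer, inner], axis=0)

    N = spec.n_landmarks
    raw = np.zeros((2 * N, spec.n_modes))
    # mode 1: canal narrowing (inward radial motion of inner contour)
    d = inner - ic
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    m = np.zeros((N, 2))
    m[spec.n_outer :] = -d
    raw[:, 0] = m.reshape(-1)
    th_o = 2.0 * np.pi * np.arange(spec.n_outer) / spec.n_outer
    extra = []
    # anisotropic scaling of the outer contour
    m = np.zeros((N, 2))
    m[: spec.n_outer] = (outer - oc) * np.array([1.0, -1.0])
    extra.append(m)
    # bending: row shift quadratic in column offset
    m = np.zeros((N, 2))
    m[: spec.n_outer, 0] = ((outer[:, 1] - oc[1]) / max(cols, 1)) ** 2
    extra.append(m)
    # low-frequency radial ripples for any further modes
    k = 2
    while len(extra) + 1 < spec.n_modes:
        m = np.zeros((N, 2))
        d_o = outer - oc
        d_o /= np.linalg.norm(d_o, axis=1, keepdims=True)
        m[: spec.n_outer] = d_o * np.cos(k * th_o)[:, None]
        extra.append(m)
        k += 1
    for j in range(1, spec.n_modes):
        raw[:, j] = extra[j - 1].reshape(-1)
    # remove any net translation (shape variation, not position) so the
    # modes live in the centroid-aligned subspace a PDM fit sees
    raw2 = raw.reshape(N, 2, -1)
    raw2 -= raw2.mean(axis=0, keepdims=True)
    raw = raw2.reshape(2 * N, -1)
    # Gram-Schmidt in given order; QR keeps mode order, fix signs
    Q, R = np.linalg.qr(raw)
    Q = Q * np.sign(np.diag(R))

    eig = np.asarray(spec.mode_std[: spec.n_modes], dtype=float) ** 2
    model = ShapeModel(
        mean=mean_pts.reshape(-1),
        components=Q,
        eigenvalues=eig,
        mean_centroid=mean_pts.mean(axis=0),
    )
    params = RendererParams(
        outer_center=oc, inner_center=ic, n_outer=spec.n_outer, n_inner=spec.n_inner
    )
    return model, params


def _fill(canvas: np.ndarray, pts: np.ndarray, value: float) -> None:
    rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape=canvas.shape)
    canvas[rr, cc] = value


def grade_of(spec: PhantomSpec, b0: float) -> int:
    t1, t2 = spec.grade_thresholds
    return 0 if b0 <= t1 else (1 if b0 <= t2 else 2)


def render_instance(
    model: ShapeModel,
    b_true: np.ndarray,
    spec: PhantomSpec,
    params: RendererParams,
    instance: int = 0,
) -> tuple[np.ndarray, Shape, int]:
    """Deform, rasterize, texture and noise one phantom instance.

    Returns ``(image in [0,1], landmark Shape, integer grade)``.  Noise is
    drawn from the counter-``instance`` substream of the spec seed.
    """
    b_true = np.asarray(b_true, dtype=float)
    pts = model.reconstruct(
        np.pad(b_true, (0, model.n_components - b_true.size))
    ).reshape(-1, 2)
    shape = Shape(pts)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(instance + 1,))
    )
    img = np.full(spec.image_size, params.background)
    b0 = float(b_true[0]) if b_true.size else 0.0
    s1 = spec.mode_std[0]
    disc = np.clip(
        params.disc_intensity + params.grade_intensity_gain * np.tanh(b0 / s1),
        0.0,
        1.0,
    )
    _fill(img, pts[: params.n_outer], disc)
    _fill(img, pts[params.n_outer :], params.canal_intensity)
    if params.edge_smoothing > 0:
        img = ndimage.gaussian_filter(img, params.edge_smoothing)
    if spec.texture_amplitude > 0:
        tex = rng.normal(size=spec.image_size)
        tex = ndimage.gaussian_filter(tex, spec.texture_smoothness)
        sd = tex.std()
        if sd > 0:
            img = img + spec.texture_amplitude * tex / sd
    if spec.noise_std > 0:
        img = img + rng.normal(0.0, spec.noise_std, size=spec.image_size)
    return np.clip(img, 0.0, 1.0), shape, grade_of(spec, b0)


@dataclass
class SyntheticDataset:
    spec: PhantomSpec
    images: list[np.ndarray]
    shapes: list[Shape]
    grades: np.ndarray  # (M,) int
    b_true: np.ndarray  # (M, n_modes)
    model: ShapeModel = None
    params: RendererParams = None

    @property
    def M(self) -> int:
        return len(self.images)


def generate_dataset(
    spec: PhantomSpec, M: int, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Sample M instances with b ~ N(0, diag(mode_std^2)), render, and
    optionally write ``images/*.png``, ``landmarks/*.pts``, ``labels.csv``
    and a ``manifest.json`` to ``out_dir``."""
    if M < 1:
        raise ValueError("M must be >= 1")
    model, params = make_generating_model(spec)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(0,))
    )
    b = rng.normal(size=(M, spec.n_modes)) * np.asarray(
        spec.mode_std[: spec.n_modes]
    )
    images, shapes, grades = [], [], []
    for i in range(M):
        img, shp, g = render_instance(model, b[i], spec, params, instance=i)
        images.append(img)
        shapes.append(shp)
        grades.append(g)
    ds = SyntheticDataset(
        spec=spec,
        images=images,
        shapes=shapes,
        grades=np.asarray(grades, dtype=int),
        b_true=b,
        model=model,
        params=params,
    )
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: SyntheticDataset, out: Path) -> None:
    from .io import write_image, write_pts

    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "landmarks").mkdir(parents=True, exist_ok=True)
    with open(out / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "grade"])
        for i, g in enumerate(ds.grades):
            name = f"{i:04d}"
            write_image(ds.images[i], out / "images" / f"{name}.png")
            write_pts(ds.shapes[i], out / "landmarks" / f"{name}.pts")
            w.writerow([name, GRADE_NAMES[g]])
    spec_d = asdict(ds.spec)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"phantom_spec": spec_d, "n_instances": ds.M}, fh, indent=2)
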