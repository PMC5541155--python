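"""Appearance pyramids: multi-scale local patches anchored at landmarks.

A landmark's *local feature pyramid* is a stack of p-by-p patches sampled
from successive pyramid levels around the landmark; because each level
halves the resolution, the same pixel footprint covers an octave-larger
anatomical region per level.  The *appearance pyramid* (AP) is the assembly
of all retained patches over landmarks and scales, flattened into one
fixed-length vector — the model's appearance observation.

Coordinates are 0-based ``(row, col)`` in the level-1 (full resolution)
frame, origin top-left, pixel centers at integers; the level-l sampling
center is ``x / 2**(l-1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .pyramids import ImagePyramid, SpectralWindowSet, reconstruct_from_wavelet, level_shape

__all__ = [
    "Shape",
    "Patch",
    "ScaleIndexSets",
    "AppearancePyramid",
    "extract_patch",
    "extract_appearance_pyramid",
    "vectorize",
    "devectorize",
    "trim_scale_sets",
    "reconstruct_appearance",
]


@dataclass
class Shape:
    """Ordered landmark configuration: N points, (row, col), subpixel."""

    points: np.ndarray  # (N, 2) float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (N, 2)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def as_vector(self) -> np.ndarray:
        """Flatten to the 2N vector [r1, c1, r2, c2, ...]."""
        return self.points.reshape(-1).copy()

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "Shape":
        return cls(np.asarray(v, dtype=float).reshape(-1, 2))

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class Patch:
    pixels: np.ndarray  # (p, p)
    landmark_index: int
    level: int


@dataclass
class ScaleIndexSets:
    """Per-landmark retained scale indices K_n (1-based levels).

    Level 1 is always retained; coarser levels may be trimmed away when
    redundant with a neighbouring landmark's patch at the same level.
    """

    sets: list[tuple[int, ...]]

    def __post_init__(self) -> None:
        norm = []
        for k in self.sets:
            kk = tuple(sorted(set(int(l) for l in k)))
            if not kk:
                raise ValueError("each K_n must be non-empty")
            if kk[0] != 1:
                raise ValueError("level 1 must be retained at every landmark")
            norm.append(kk)
        self.sets = norm

    @classmethod
    def full(cls, N: int, L: int) -> "ScaleIndexSets":
        return cls([tuple(range(1, L + 1))] * N)

    @property
    def n_landmarks(self) -> int:
        return len(self.sets)

    def n_patches(self) -> int:
        return sum(len(k) for k in self.sets)

    def index_pairs(self) -> list[tuple[int, int]]:
        """Canonical (n, l) order: landmark-major, level-minor."""
        return [(n, l) for n, k in enumerate(self.sets) for l in k]


@dataclass
class AppearancePyramid:
    """The assembly of retained patches, in canonical (n-major, l-minor) order."""

    patches: list[Patch]
    K: ScaleIndexSets
    patch_size: int
    source_shape: Shape | None = None

    def __post_init__(self) -> None:
        if len(self.patches) != self.K.n_patches():
            raise ValueError("patch count does not match scale index sets")

    def patch(self, n: int, l: int) -> Patch:
        i = self.K.index_pairs().index((n, l))
        return self.patches[i]


def extract_patch(
    pyramid: ImagePyramid, x: np.ndarray, l: int, p: int
) -> Patch:
    """Sample a p-by-p patch of level ``l`` centered at ``x / 2**(l-1)``.

    Bilinear interpolation; samples outside the level replicate the edge.
    """
    if p % 2 != 1:
        raise ValueError("patch size p must be odd")
    if not 1 <= l <= pyramid.L:
        raise ValueError(f"level {l} outside pyramid (L={pyramid.L})")
    c = np.asarray(x, dtype=float) / 2 ** (l - 1)
    h = p // 2
    off = np.arange(-h, h + 1, dtype=float)
    rows = c[0] + off
    cols = c[1] + off
    grid = np.meshgrid(rows, cols, indexing="ij")
    pix = ndimage.map_coordinates(
        pyramid.levels[l - 1], np.stack([g.ravel() for g in grid]),
        order=1, mode="nearest",
    ).reshape(p, p)
    return Patch(pixels=pix, landmark_index=-1, level=l)


def extract_appearance_pyramid(
    pyramid: ImagePyramid, s: Shape, K: ScaleIndexSets, p: int
) -> AppearancePyramid:
    """Extract every retained patch (n, l in K_n) at the landmarks of ``s``."""
    if s.n_points != K.n_landmarks:
        raise ValueError(
            f"shape has {s.n_points} landmarks, scale sets expect {K.n_landmarks}"
        )
    patches = []
    for n, l in K.index_pairs():
        pt = extract_patch(pyramid, s.points[n], l, p)
        pt.landmark_index = n
        patches.append(pt)
    return AppearancePyramid(patches=patches, K=K, patch_size=p, source_shape=s)


def vectorize(ap: AppearancePyramid) -> np.ndarray:
    """Flatten to the fixed-length observation vector (row-major per patch)."""
    return np.concatenate([pt.pixels.reshape(-1) for pt in ap.patches])


def devectorize(
    v: np.ndarray, K: ScaleIndexSets, p: int
) -> AppearancePyramid:
    """Inverse of :func:`vectorize` given the model geometry."""
    v = np.asarray(v, dtype=float)
    if v.size != K.n_patches() * p * p:
        raise ValueError("vector length does not match geometry")
    patches = []
    for i, (n, l) in enumerate(K.index_pairs()):
        block = v[i * p * p : (i + 1) * p * p].reshape(p, p)
        patches.append(Patch(pixels=block.copy(), landmark_index=n, level=l))
    return AppearancePyramid(patches=patches, K=K, patch_size=p)


def block_slices(K: ScaleIndexSets, p: int) -> dict[tuple[int, int], slice]:
    """Map (n, l) -> slice of that patch's entries in the vectorized AP."""
    return {
        (n, l): slice(i * p * p, (i + 1) * p * p)
        for i, (n, l) in enumerate(K.index_pairs())
    }


def _normalized(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 1e-12 else v


def trim_scale_sets(
    training_aps: list[AppearancePyramid],
    threshold: float,
    mean_shape: Shape | None = None,
    n_neighbours: int = 2,
) -> ScaleIndexSets:
    """Greedily drop coarse patches redundant with their neighbours' patches.

    At each step, every retained patch at level >= 2 is scored by the mean
    (over training samples) normalized L2 distance to the nearest retained
    same-level patch among its ``n_neighbours`` spatially nearest landmarks
    (by mean-shape distance).  The least-distance patch is deleted while that
    least distance is below ``threshold``; level-1 patches are never removed.
    Ties break on lowest landmark index, then lowest level.
    """
    if not training_aps:
        raise ValueError("need at least one training appearance pyramid")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    K0 = training_aps[0].K
    N = K0.n_landmarks
    if mean_shape is None:
        shapes = [ap.source_shape for ap in training_aps]
        if any(s is None for s in shapes):
            raise ValueError("training APs must carry source shapes (or pass mean_shape)")
        mean_shape = Shape(np.mean([s.points for s in shapes], axis=0))

    # neighbour landmark indices by mean-shape distance
    d2 = np.sum(
        (mean_shape.points[:, None, :] - mean_shape.points[None, :, :]) ** 2, axis=-1
    )
    np.fill_diagonal(d2, np.inf)
    nbrs = [tuple(np.argsort(d2[n])[:n_neighbours]) for n in range(N)]

    # normalized patch stacks per (n, l): (M, p*p)
    stacks: dict[tuple[int, int], np.ndarray] = {}
    for n, l in K0.index_pairs():
        stacks[(n, l)] = np.stack(
            [_normalized(ap.patch(n, l).pixels.reshape(-1)) for ap in training_aps]
        )

    retained = {pair: True for pair in K0.index_pairs()}

    def score(n: int, l: int) -> float:
        cands = [m for m in nbrs[n] if retained.get((m, l), False)]
        if not cands:
            # every neighbour already trimmed at this level: redundancy is
            # transitive, so fall back to their (untrimmed) training patches
            cands = list(nbrs[n])
        if not cands:
            return np.inf
        per_sample_best = np.min(
            [np.linalg.norm(stacks[(n, l)] - stacks[(m, l)], axis=1) for m in cands],
            axis=0,
        )
        return float(per_sample_best.mean())

    while True:
        cand = [
            (score(n, l), n, l)
            for (n, l), keep in retained.items()
            if keep and l >= 2
        ]
        if not cand:
            break
        best = min(cand)  # tuple order = ties by landmark then level
        if not best[0] < threshold:
            break
        retained[(best[1], best[2])] = False

    sets = [
        tuple(l for (n, l), keep in retained.items() if keep and n == i)
        for i in range(N)
    ]
    return ScaleIndexSets(sets)


def _splat_patch(
    canvas: np.ndarray, weight: np.ndarray, pixels: np.ndarray, center: np.ndarray
) -> None:
    """Bilinearly distribute a patch onto the canvas around ``center``."""
    p = pixels.shape[0]
    h = p // 2
    r0f, c0f = center[0] - h, center[1] - h
    ri, ci = int(np.floor(r0f)), int(np.floor(c0f))
    fr, fc = r0f - ri, c0f - ci
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        if w == 0.0:
            continue
        rs, cs = ri + dr, ci + dc
        rlo, rhi = max(rs, 0), min(rs + p, canvas.shape[0])
        clo, chi = max(cs, 0), min(cs + p, canvas.shape[1])
        if rlo >= rhi or clo >= chi:
            continue
        pr = slice(rlo - rs, rhi - rs)
        pc = slice(clo - cs, chi - cs)
        canvas[rlo:rhi, clo:chi] += w * pixels[pr, pc]
        weight[rlo:rhi, clo:chi] += w


def reconstruct_appearance(
    ap: AppearancePyramid,
    s: Shape,
    pyramid_kind: str,
    windows: SpectralWindowSet | None = None,
    base_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Paint the patches back onto level canvases and accumulate the scales.

    Per level, each patch is pasted (bilinear splat, overlaps averaged by
    coverage) at ``x / 2**(l-1)``.  Wavelet pyramids then run the synthesis
    accumulation (pad spectra, re-window, sum); Gaussian pyramids return the
    level-1 canvas, the coarser levels being redundant context.
    """
    if pyramid_kind == "wavelet" and windows is None:
        raise ValueError("wavelet reconstruction needs the spectral windows")
    if base_shape is None:
        if windows is not None:
            base_shape = tuple(windows.base_shape)
        else:
            raise ValueError("base_shape required for gaussian reconstruction")
    L = max(max(k) for k in ap.K.sets)
    canvases = []
    for l in range(1, L + 1):
        shp = level_shape(base_shape, l)
        canvas = np.zeros(shp)
        weight = np.zeros(shp)
        for pt in ap.patches:
            if pt.level != l:
                continue
            center = s.points[pt.landmark_index] / 2 ** (l - 1)
            _splat_patch(canvas, weight, pt.pixels, center)
        nz = weight > 1e-12
        canvas[nz] /= weight[nz]
        canvases.append(canvas)
    if pyramid_kind == "gaussian":
        return canvases[0]
    wl_levels = canvases + [
        np.zeros(level_shape(base_shape, l)) for l in range(L + 1, windows.L + 1)
    ]
    pyr = ImagePyramid(levels=wl_levels, kind="wavelet")
    return reconstruct_from_wavelet(pyr, windows)
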