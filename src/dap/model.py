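"""Trained DAP model container and training entry point.

A :class:`DAPModel` bundles the pyramid geometry (kind, levels, patch size,
retained scale sets), the PCA priors over shape and appearance, and —
for the implicit fitter — an SDM cascade.  Training extracts appearance
pyramids from annotated images, optionally trims redundant coarse patches,
and fits the priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .appearance import (
    AppearancePyramid,
    ScaleIndexSets,
    Shape,
    extract_appearance_pyramid,
    trim_scale_sets,
    vectorize,
)
from .priors import (
    AppearanceModel,
    ShapeModel,
    fit_appearance_model,
    fit_shape_model,
)
from .pyramids import (
    ImagePyramid,
    SpectralWindowSet,
    build_gaussian_pyramid,
    build_spectral_windows,
    build_wavelet_pyramid,
)

__all__ = ["ModelGeometry", "DAPModel", "train_dap_model"]


@dataclass
class ModelGeometry:
    """Pyramid and patch geometry shared by every DAP component."""

    kind: str  # "gaussian" | "wavelet"
    L: int
    p: int
    K: ScaleIndexSets
    gaussian_sigma: float = 1.0
    transition_width: float = 0.5
    _window_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "wavelet"):
            raise ValueError(f"unknown pyramid kind {self.kind!r}")
        if self.p % 2 != 1:
            raise ValueError("patch size p must be odd")

    @property
    def n_landmarks(self) -> int:
        return self.K.n_landmarks

    def windows_for(self, base_shape: tuple[int, int]) -> SpectralWindowSet:
        key = tuple(base_shape)
        if key not in self._window_cache:
            self._window_cache[key] = build_spectral_windows(
                key, self.L, self.transition_width
            )
        return self._window_cache[key]

    def build_pyramid(self, image: np.ndarray) -> ImagePyramid:
        if self.kind == "gaussian":
            return build_gaussian_pyramid(image, self.L, self.gaussian_sigma)
        return build_wavelet_pyramid(image, self.windows_for(np.asarray(image).shape))

    def extract(self, pyramid: ImagePyramid, s: Shape) -> AppearancePyramid:
        return extract_appearance_pyramid(pyramid, s, self.K, self.p)


@dataclass
class DAPModel:
    """Geometry + statistical priors (+ optional SDM cascade)."""

    geometry: ModelGeometry
    shape_model: ShapeModel
    appearance_model: AppearanceModel
    cascade: Optional[object] = None  # SDMCascade, attached by sdm.train_sdm

    def observation(self, pyramid: ImagePyramid, s: Shape) -> np.ndarray:
        """Normalized, vectorized appearance pyramid at shape ``s``."""
        a = vectorize(self.geometry.extract(pyramid, s))
        return self.appearance_model.normalize(a)


def train_dap_model(
    images: list[np.ndarray],
    shapes: list[Shape],
    kind: str = "wavelet",
    L: int = 3,
    p: int = 17,
    shape_variance: float = 0.95,
    appearance_variance: float = 0.95,
    trim_threshold: float = 0.0,
    normalization: str = "zscore",
    gaussian_sigma: float = 1.0,
    transition_width: float = 0.5,
) -> DAPModel:
    """Fit the DAP priors from annotated images.

    With ``trim_threshold > 0`` the coarse-level patch sets are trimmed on
    the training appearance pyramids before the appearance PCA.
    """
    if len(images) != len(shapes) or len(images) < 2:
        raise ValueError("need >= 2 (image, shape) training pairs")
    N = shapes[0].n_points
    geom = ModelGeometry(
        kind=kind,
        L=L,
        p=p,
        K=ScaleIndexSets.full(N, L),
        gaussian_sigma=gaussian_sigma,
        transition_width=transition_width,
    )
    pyramids = [geom.build_pyramid(im) for im in images]
    aps = [geom.extract(pyr, s) for pyr, s in zip(pyramids, shapes)]
    if trim_threshold > 0.0:
        geom.K = trim_scale_sets(aps, trim_threshold)
        aps = [geom.extract(pyr, s) for pyr, s in zip(pyramids, shapes)]
    appearance_model = fit_appearance_model(
        [vectorize(ap) for ap in aps],
        variance_fraction=appearance_variance,
        normalization=normalization,
    )
    shape_model = fit_shape_model(shapes, variance_fraction=shape_variance)
    return DAPModel(
        geometry=geom, shape_model=shape_model, appearance_model=appearance_model
    )
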