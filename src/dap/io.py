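"""File I/O: PTS landmark files, images, model archives, run configuration.

Landmarks interchange in the PTS points format (``version: 1`` header,
1-based ``x y`` floats); internally everything is 0-based ``(row, col)``
with the conversion done only at this boundary.  Trained models serialize
to a single ``.npz`` archive holding the arrays plus a JSON metadata
record.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .appearance import ScaleIndexSets, Shape
from .model import DAPModel, ModelGeometry
from .priors import AppearanceModel, ShapeModel
from .sdm import SDMCascade, SDMStage

__all__ = [
    "read_pts",
    "write_pts",
    "read_image",
    "write_image",
    "save_model",
    "load_model",
    "RunConfig",
    "write_manifest",
]

ARCHIVE_VERSION = "dap-model-1"


def read_pts(path: str | Path, expected_n: int | None = None) -> Shape:
    """Read a version-1 PTS file; converts 1-based (x, y) to 0-based (row, col)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].lower().startswith("version:"):
        raise ValueError(f"{path}: missing PTS version header")
    if lines[0].split(":")[1].strip() != "1":
        raise ValueError(f"{path}: unsupported PTS version")
    if not lines[1].lower().startswith("n_points:"):
        raise ValueError(f"{path}: missing n_points header")
    n = int(lines[1].split(":")[1])
    body = [ln for ln in lines[2:] if ln not in ("{", "}")]
    if len(body) != n:
        raise ValueError(f"{path}: expected {n} points, found {len(body)}")
    pts = []
    for ln in body:
        x, y = (float(t) for t in ln.split()[:2])
        pts.append((y - 1.0, x - 1.0))
    if expected_n is not None and n != expected_n:
        raise ValueError(f"{path}: {n} points, model expects {expected_n}")
    return Shape(np.asarray(pts))


def write_pts(shape: Shape, path: str | Path) -> None:
    """Write landmarks as a version-1 PTS file (1-based x y)."""
    with open(path, "w") as fh:
        fh.write(f"version: 1\nn_points: {shape.n_points}\n{{\n")
        for r, c in shape.points:
            fh.write(f"{c + 1.0:.6f} {r + 1.0:.6f}\n")
        fh.write("}\n")


def read_image(path: str | Path) -> np.ndarray:
    """Load a single-channel PNG/TIFF as float in [0, 1]."""
    with Image.open(path) as im:
        if im.mode not in ("L", "I", "I;16", "F"):
            im = im.convert("F")
        arr = np.asarray(im, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image")
    if arr.max() > 1.0:
        arr = arr / (65535.0 if arr.max() > 255.0 else 255.0)
    return arr


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a float image in [0, 1] as 8-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8), mode="L").save(path)


def save_model(model: DAPModel, path: str | Path) -> None:
    """Serialize geometry, priors and any cascade to one .npz archive."""
    geom = model.geometry
    meta = {
        "version": ARCHIVE_VERSION,
        "kind": geom.kind,
        "L": geom.L,
        "p": geom.p,
        "N": geom.n_landmarks,
        "gaussian_sigma": geom.gaussian_sigma,
        "transition_width": geom.transition_width,
        "K": [list(k) for k in geom.K.sets],
        "normalization": model.appearance_model.normalization,
        "has_cascade": model.cascade is not None,
    }
    arrays = {
        "meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        "shape_mean": model.shape_model.mean,
        "shape_components": model.shape_model.components,
        "shape_eigenvalues": model.shape_model.eigenvalues,
        "shape_mean_centroid": model.shape_model.mean_centroid,
        "app_mean": model.appearance_model.mean,
        "app_components": model.appearance_model.components,
        "app_eigenvalues": model.appearance_model.eigenvalues,
    }
    if model.cascade is not None:
        c = model.cascade
        arrays["sdm_s0"] = c.s0
        arrays["sdm_training_errors"] = np.asarray(c.training_errors)
        meta["sdm"] = {
            "feature": c.feature,
            "hog_cells": c.hog_cells,
            "hog_bins": c.hog_bins,
            "ridge_weight": c.ridge_weight
            if isinstance(c.ridge_weight, str)
            else float(c.ridge_weight),
            "n_stages": c.n_stages,
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        for i, st in enumerate(c.stages):
            arrays[f"sdm_R_{i}"] = st.R
            arrays[f"sdm_b_{i}"] = st.b
    np.savez_compressed(path, **arrays)


def load_model(path: str | Path) -> DAPModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        if meta.get("version") != ARCHIVE_VERSION:
            raise ValueError(f"{path}: unsupported model archive version")
        geom = ModelGeometry(
            kind=meta["kind"],
            L=int(meta["L"]),
            p=int(meta["p"]),
            K=ScaleIndexSets([tuple(k) for k in meta["K"]]),
            gaussian_sigma=float(meta["gaussian_sigma"]),
            transition_width=float(meta["transition_width"]),
        )
        shape_model = ShapeModel(
            mean=z["shape_mean"],
            components=z["shape_components"],
            eigenvalues=z["shape_eigenvalues"],
            mean_centroid=z["shape_mean_centroid"],
        )
        appearance_model = AppearanceModel(
            mean=z["app_mean"],
            components=z["app_components"],
            eigenvalues=z["app_eigenvalues"],
            normalization=meta["normalization"],
        )
        model = DAPModel(
            geometry=geom, shape_model=shape_model, appearance_model=appearance_model
        )
        if meta.get("has_cascade"):
            sm = meta["sdm"]
            stages = [
                SDMStage(R=z[f"sdm_R_{i}"], b=z[f"sdm_b_{i}"], feature=sm["feature"])
                for i in range(int(sm["n_stages"]))
            ]
            model.cascade = SDMCascade(
                stages=stages,
                s0=z["sdm_s0"],
                feature=sm["feature"],
                hog_cells=int(sm["hog_cells"]),
                hog_bins=int(sm["hog_bins"]),
                ridge_weight=sm["ridge_weight"],
                training_errors=list(z["sdm_training_errors"]),
            )
    return model


@dataclass
class RunConfig:
    """Validated pipeline configuration, serialized into every manifest."""

    pyramid: str = "wavelet"  # gaussian | wavelet
    levels: int = 3
    patch_size: int = 17
    shape_variance: float = 0.95
    appearance_variance: float = 0.95
    trim_threshold: float = 0.0
    fitter: str = "sdm"  # explicit | sdm
    sdm_stages: int = 4
    sdm_feature: str = "hog"
    ridge_weight: str | float = "auto"
    hog_cells: int = 4
    hog_bins: int = 9
    outer_iters: int = 10
    classifier_cycles: int = 100
    feature_space_variance: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pyramid not in ("gaussian", "wavelet"):
            raise ValueError(f"pyramid must be gaussian|wavelet, got {self.pyramid!r}")
        if self.fitter not in ("explicit", "sdm"):
            raise ValueError(f"fitter must be explicit|sdm, got {self.fitter!r}")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.patch_size < 3 or self.patch_size % 2 != 1:
            raise ValueError("patch_size must be odd and >= 3")
        for name in ("shape_variance", "appearance_variance", "feature_space_variance"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.sdm_feature not in ("hog", "intensity"):
            raise ValueError("sdm_feature must be hog|intensity")
        if self.trim_threshold < 0:
            raise ValueError("trim_threshold must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def write_manifest(path: str | Path, config: RunConfig, **extra) -> None:
    """Record config + seed + versions next to every pipeline output."""
    import dap

    payload = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {"dap": dap.__version__, "numpy": np.__version__},
    }
    payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
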