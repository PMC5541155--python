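"""Landmark-detection evaluation: point-to-boundary distance and Dice.

PtoBD measures, per fitted landmark, the Euclidean distance to the nearest
point of the ground-truth contour polyline of its anatomical group (units:
pixels).  DSC rasterizes the fitted and true region polygons on the image
grid and scores the pixel overlap ``2 tp / (2 tp + fp + fn)``.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LineString, LinearRing, Point, Polygon
from skimage.draw import polygon as draw_polygon

from .appearance import Shape

__all__ = ["point_to_boundary", "dice_coefficient"]


def point_to_boundary(
    shape: Shape,
    truth_contours: list[np.ndarray],
    groups: list[np.ndarray] | None = None,
    closed: bool = True,
) -> tuple[np.ndarray, float]:
    """Distance from each landmark to its group's ground-truth contour.

    ``truth_contours[g]`` is a (P, 2) polyline of (row, col) vertices;
    ``groups[g]`` lists the landmark indices evaluated against it (default:
    every landmark against a single contour).  Returns (per-landmark
    distances, mean).
    """
    if not truth_contours:
        raise ValueError("need at least one ground-truth contour")
    if groups is None:
        if len(truth_contours) != 1:
            raise ValueError("groups required with multiple contours")
        groups = [np.arange(shape.n_points)]
    dists = np.full(shape.n_points, np.nan)
    for contour, idx in zip(truth_contours, groups):
        contour = np.asarray(contour, dtype=float)
        if contour.shape[0] < 2:
            raise ValueError("contour needs at least 2 vertices")
        geom = (
            LinearRing(contour) if closed and contour.shape[0] >= 3
            else LineString(contour)
        )
        for n in np.asarray(idx, dtype=int):
            dists[n] = geom.distance(Point(shape.points[n]))
    if np.any(np.isnan(dists)):
        raise ValueError("groups do not cover every landmark")
    return dists, float(dists.mean())


def _mask(pts: np.ndarray, grid: tuple[int, int], validate: bool) -> np.ndarray:
    if validate and not Polygon(pts).is_valid:
        raise ValueError("polygon is self-intersecting")
    m = np.zeros(grid, dtype=bool)
    rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape=grid)
    m[rr, cc] = True
    return m


def dice_coefficient(
    fitted: Shape,
    truth: Shape,
    regions: dict[str, np.ndarray],
    grid: tuple[int, int],
) -> tuple[dict[str, float], float]:
    """DSC per anatomical region (landmark-index polygons) and their mean.

    The ground-truth polygon must be simple; a fitted polygon is rasterized
    as-is (a slightly twisted prediction is a legitimate, if poor, fit).
    """
    out = {}
    for name, idx in regions.items():
        idx = np.asarray(idx, dtype=int)
        mf = _mask(fitted.points[idx], grid, validate=False)
        mt = _mask(truth.points[idx], grid, validate=True)
        tp = float(np.sum(mf & mt))
        fp = float(np.sum(mf & ~mt))
        fn = float(np.sum(~mf & mt))
        denom = 2.0 * tp + fp + fn
        out[name] = 2.0 * tp / denom if denom > 0 else 1.0
    return out, float(np.mean(list(out.values())))
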