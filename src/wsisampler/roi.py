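"""ROI prediction: DBSCAN clustering of tumour points, convex hulls, Dice.

Tumour-predicted patch centres (after false-positive correction) form a
point cloud. DBSCAN groups dense runs of points into clusters and rejects
sporadic points without multiple neighbours within the 2000 px radius, so
isolated misclassifications never contribute to the predicted region. Each
cluster's convex hull is one predicted ROI polygon; agreement with the
ground-truth outline is scored with the Dice / F1 coefficient on rasterized
areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon
from shapely.geometry.polygon import orient
from shapely.ops import unary_union
from sklearn.cluster import DBSCAN

from .errors import ParameterError

logger = logging.getLogger(__name__)

DEFAULT_EPS_PX = 2000.0
DEFAULT_MIN_SAMPLES = 3


@dataclass
class RoiEstimate:
    """DBSCAN clusters of tumour points plus their convex-hull polygons."""

    clusters: list[np.ndarray] = field(default_factory=list)
    noise_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    hulls: list[Polygon] = field(default_factory=list)
    eps_px: float = DEFAULT_EPS_PX
    min_samples: int = DEFAULT_MIN_SAMPLES

    def hull_union(self):
        return unary_union(self.hulls) if self.hulls else Polygon()


def dbscan_cluster(
    points: np.ndarray,
    eps_px: float = DEFAULT_EPS_PX,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> np.ndarray:
    """Cluster (n, 2) points with standard DBSCAN semantics.

    A core point has at least ``min_samples`` points (itself included)
    within ``eps_px``; clusters are connected core points plus their border
    points. Returns one integer label per point, -1 for noise.
    """
    if eps_px <= 0:
        raise ParameterError(f"eps_px must be > 0, got {eps_px}")
    if min_samples < 2:
        raise ParameterError(f"min_samples must be >= 2, got {min_samples}")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if points.shape[0] == 0:
        return np.empty(0, dtype=int)
    return DBSCAN(eps=eps_px, min_samples=min_samples).fit(points).labels_


def build_hulls(clusters: list[np.ndarray]) -> list[Polygon]:
    """One convex hull per cluster with at least 3 non-collinear points.

    Degenerate clusters (fewer than 3 points, or all collinear) are dropped
    with a log entry. Hull vertices are in counter-clockwise order.
    """
    hulls: list[Polygon] = []
    for i, pts in enumerate(clusters):
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        if pts.shape[0] < 3:
            logger.info("cluster %d dropped: only %d point(s)", i, pts.shape[0])
            continue
        hull = MultiPoint(pts).convex_hull
        if not isinstance(hull, Polygon) or hull.area == 0:
            logger.info("cluster %d dropped: degenerate (collinear) hull", i)
            continue
        hulls.append(orient(hull, sign=1.0))
    return hulls


def estimate_roi(
    points: np.ndarray,
    eps_px: float = DEFAULT_EPS_PX,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> RoiEstimate:
    """Cluster tumour points and build hull polygons in one step."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    labels = dbscan_cluster(points, eps_px, min_samples)
    clusters = [points[labels == k] for k in sorted(set(labels) - {-1})]
    return RoiEstimate(
        clusters=clusters,
        noise_points=points[labels == -1],
        hulls=build_hulls(clusters),
        eps_px=eps_px,
        min_samples=min_samples,
    )


def dice_roi(
    pred_polygons: list[Polygon],
    gt_polygon: Polygon | None,
    slide_dims: tuple[int, int],
    raster_step: int = 32,
) -> float:
    """Dice / F1 overlap between predicted and ground-truth ROI areas.

    Both regions are rasterized on the slide's raster lattice of cell
    centres and Dice = 2|P∩G| / (|P| + |G|) computed on cell counts. Two
    empty regions agree vacuously (1.0); one empty region scores 0.0.
    """
    width, height = slide_dims
    d = raster_step
    pred = unary_union([p for p in pred_polygons if p is not None and not p.is_empty]) \
        if pred_polygons else Polygon()
    gt = gt_polygon if gt_polygon is not None else Polygon()
    if pred.is_empty and gt.is_empty:
        return 1.0
    if pred.is_empty or gt.is_empty:
        return 0.0
    cx = (np.arange(int(np.ceil(width / d))) + 0.5) * d
    cy = (np.arange(int(np.ceil(height / d))) + 0.5) * d
    xs, ys = np.meshgrid(cx, cy)
    in_pred = shapely.contains_xy(pred, xs, ys)
    in_gt = shapely.contains_xy(gt, xs, ys)
    denom = int(in_pred.sum()) + int(in_gt.sum())
    if denom == 0:
        return 1.0  # both rasterize to nothing at this resolution
    return 2.0 * int((in_pred & in_gt).sum()) / denom


def hulls_to_geojson(hulls: list[Polygon]) -> dict:
    """Predicted ROI hulls as a GeoJSON FeatureCollection (pixel coords)."""
    from shapely.geometry import mapping

    return {
        "type": "FeatureCollection",
        "crs": "pixel:level0",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(h),
                "properties": {"role": "predicted_roi", "cluster_id": i},
            }
            for i, h in enumerate(hulls)
        ],
    }
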