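"""Photoreceptor-based mosaic metrics.

From a set of cone coordinates this module computes the four standard
mosaic descriptors:

* **density** — cones per mm² of ROI area;
* **hexagonality** — percentage of cones whose Voronoi cell has 6 ± 1
  neighbors, a packing-regularity measure (perfect triangular packing gives
  hexagonal cells, n = 6);
* **ICD** (intercell distance) — mean Delaunay-triangulation edge length;
* **NND** (nearest-neighbor distance) — mean distance from each cone to its
  closest neighbor.

Cells that are unbounded or clipped by the ROI boundary have censored
neighbor counts and are excluded from the hexagonality denominator.
Metrics that are undefined for too few cones are reported as NaN sentinels,
never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, Voronoi, cKDTree

from .detection import ConeSet, DetectionParams, detect_cones, to_16bit_sharpened
from .geometry import ROISpec
from .image import RetinalImage


@dataclass
class MosaicMetrics:
    """Summary metrics for one ROI plus the per-cone table.

    ``per_cone`` has columns ``x_um, y_um, neighbors, nnd_um, bounded``;
    ``neighbors`` is NaN where fewer than 4 cones exist, ``bounded`` flags
    cones whose Voronoi cell is finite and inside the ROI.
    """

    n_cones: int
    density_cones_per_mm2: float
    hexagonality_pct: float
    icd_um: float
    nnd_um: float
    per_cone: pd.DataFrame

    def as_row(self) -> dict:
        return {
            "n_cones": self.n_cones,
            "density": self.density_cones_per_mm2,
            "hex_pct": self.hexagonality_pct,
            "icd_um": self.icd_um,
            "nnd_um": self.nnd_um,
        }


def cone_density(cones: ConeSet, roi: ROISpec) -> float:
    """Cones per mm²: count divided by ROI area, area = (side_um/1000)²."""
    area = roi.area_mm2
    if not (area > 0):
        raise ValueError("ROI area must be > 0")
    return len(cones) / area


def voronoi_neighbor_counts(
    cones: ConeSet, roi: Optional[ROISpec] = None,
    bounds_um: Optional[Tuple[float, float, float, float]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-cone Voronoi neighbor counts and bounded-cell flags.

    A cone's neighbor count is the number of tessellation cells sharing an
    edge with its cell (equivalently its Delaunay natural neighbors).  Cells
    that are unbounded, or whose vertices leave the ROI rectangle, are
    flagged ``bounded=False``: their true neighbor count is censored by the
    window and they are excluded from hexagonality statistics.

    ``bounds_um`` is (xmin, ymin, xmax, ymax); defaults to the ROI square
    [0, side]² when ``roi`` is given, else the coordinate bounding box.
    """
    pts = cones.xy
    n = len(pts)
    if n < 4:
        raise ValueError("need >= 4 cones for a Voronoi tessellation")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("degenerate (collinear) cone configuration")

    vor = Voronoi(pts)
    counts = np.zeros(n, dtype=int)
    for a, b in vor.ridge_points:
        counts[a] += 1
        counts[b] += 1

    if bounds_um is None:
        if roi is not None:
            bounds_um = (0.0, 0.0, roi.side_um, roi.side_um)
        else:
            bounds_um = (
                float(pts[:, 0].min()), float(pts[:, 1].min()),
                float(pts[:, 0].max()), float(pts[:, 1].max()),
            )
    xmin, ymin, xmax, ymax = bounds_um

    bounded = np.ones(n, dtype=bool)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if len(region) == 0 or -1 in region:
            bounded[i] = False
            continue
        verts = vor.vertices[region]
        if (
            verts[:, 0].min() < xmin or verts[:, 0].max() > xmax
            or verts[:, 1].min() < ymin or verts[:, 1].max() > ymax
        ):
            bounded[i] = False
    return counts, bounded


def hexagonality(counts: np.ndarray, bounded: Optional[np.ndarray] = None) -> float:
    """Percent of (bounded) cones with neighbor count in {5, 6, 7}.

    Returns NaN when no bounded cone exists (undefined, not zero).
    """
    counts = np.asarray(counts)
    if bounded is not None:
        counts = counts[np.asarray(bounded, dtype=bool)]
    if counts.size == 0:
        return float("nan")
    hexish = np.sum((counts >= 5) & (counts <= 7))
    return 100.0 * float(hexish) / counts.size


def _delaunay_edges(pts: np.ndarray) -> np.ndarray:
    """Unique (i, j) vertex pairs of the Delaunay triangulation."""
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    return np.array(sorted(edges), dtype=int)


def delaunay_icd(cones: ConeSet, exclude_hull: bool = False) -> float:
    """Mean Euclidean length of unique Delaunay edges (µm).

    ``exclude_hull=True`` drops edges incident to convex-hull vertices,
    removing window-elongated boundary edges.
    """
    pts = cones.xy
    if len(pts) < 3:
        raise ValueError("need >= 3 cones for a Delaunay triangulation")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("degenerate (collinear) cone configuration")
    edges = _delaunay_edges(pts)
    if exclude_hull:
        tri = Delaunay(pts)
        hull = set(np.unique(tri.convex_hull).tolist())
        keep = [k for k, (i, j) in enumerate(edges) if i not in hull and j not in hull]
        edges = edges[keep]
        if len(edges) == 0:
            return float("nan")
    d = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    return float(d.mean())


def nearest_neighbor_distance(cones: ConeSet) -> Tuple[float, np.ndarray]:
    """Per-cone distance to the closest other cone; summary = mean.

    Returns (mean_nnd_um, per_cone_nnd).  With fewer than 2 cones the mean
    is NaN and the per-cone array is empty/NaN.
    """
    pts = cones.xy
    n = len(pts)
    if n < 2:
        return float("nan"), np.full(n, np.nan)
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    per = dist[:, 1]
    return float(per.mean()), per


def metrics_from_cones(cones: ConeSet, roi: ROISpec) -> MosaicMetrics:
    """Assemble all four metrics (with per-cone table) from coordinates."""
    n = len(cones)
    density = cone_density(cones, roi)
    nnd_mean, nnd_per = nearest_neighbor_distance(cones)

    if n >= 4:
        try:
            counts, bounded = voronoi_neighbor_counts(cones, roi)
            hex_pct = hexagonality(counts, bounded)
            counts_f = counts.astype(float)
        except ValueError:
            counts_f = np.full(n, np.nan)
            bounded = np.zeros(n, dtype=bool)
            hex_pct = float("nan")
    else:
        counts_f = np.full(n, np.nan)
        bounded = np.zeros(n, dtype=bool)
        hex_pct = float("nan")

    if n >= 3:
        try:
            icd = delaunay_icd(cones)
        except ValueError:
            icd = float("nan")
    else:
        icd = float("nan")

    per_cone = pd.DataFrame(
        {
            "x_um": cones.x_um,
            "y_um": cones.y_um,
            "neighbors": counts_f,
            "nnd_um": nnd_per,
            "bounded": bounded,
        }
    )
    return MosaicMetrics(
        n_cones=n,
        density_cones_per_mm2=density,
        hexagonality_pct=hex_pct,
        icd_um=icd,
        nnd_um=nnd_mean,
        per_cone=per_cone,
    )


def analyze_roi(image: RetinalImage, roi: ROISpec, params: DetectionParams) -> MosaicMetrics:
    """Full per-ROI pipeline: 16-bit sharpen → detect cones → all metrics."""
    try:
        prepared = to_16bit_sharpened(image)
    except ValueError as e:
        raise ValueError(f"preprocessing stage failed: {e}") from e
    try:
        cones = detect_cones(prepared, params)
    except ValueError as e:
        raise ValueError(f"detection stage failed: {e}") from e
    try:
        return metrics_from_cones(cones, roi)
    except ValueError as e:
        raise ValueError(f"metrics stage failed: {e}") from e
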