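"""Minimum-convex-polygon acoustic areas and male-female dimorphism metrics.

The 95% minimum convex polygon (MCP) — a home-range estimator repurposed for
acoustic spaces — keeps the fraction of points nearest the arithmetic
centroid and takes their convex hull. Per-population sexual dimorphism is
summarized by three numbers computed from the male and female MCPs in a 2-D
embedding: area overlap (as a proportion of the combined area), distance
between sex centroids on z-scored axes, and the absolute area-size
difference as a proportion of the combined area. Unequal sex sample sizes
are handled by repeatedly subsampling the larger sex down to the smaller and
averaging.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint, Polygon
from shapely.geometry.polygon import orient

__all__ = [
    "MCPolygon",
    "DimorphismResult",
    "mcp",
    "element_diversity_scores",
    "acoustic_area_by_sex",
    "dimorphism_metrics",
    "balanced_subsample_dimorphism",
]


@dataclass
class MCPolygon:
    """Convex hull of the ``retain`` fraction of points nearest the centroid."""

    vertices: np.ndarray  # (m, 2) counter-clockwise
    area: float
    retain: float
    n_points_in: int
    n_points_used: int
    degenerate: bool = False

    @property
    def shapely(self) -> Polygon:
        if self.degenerate or len(self.vertices) < 3:
            return Polygon()
        return Polygon(self.vertices)

    @property
    def wkt(self) -> str:
        return self.shapely.wkt


def mcp(points: np.ndarray, retain: float = 0.95) -> MCPolygon:
    """95% minimum convex polygon of a 2-D point set.

    The centroid is the arithmetic mean of *all* points; points are ranked by
    Euclidean distance to it and the nearest ``ceil(retain * n)`` retained
    (ties at the cut resolved by input order), then hulled. Hulls with fewer
    than three non-collinear points get area 0 and the degenerate flag.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    if not 0 < retain <= 1:
        raise ValueError("retain must be in (0, 1]")
    n = len(pts)
    n_used = math.ceil(retain * n)
    centroid = pts.mean(axis=0)
    dist = np.linalg.norm(pts - centroid, axis=1)
    keep = np.argsort(dist, kind="stable")[:n_used]
    kept = pts[np.sort(keep)]  # input order among retained
    hull = MultiPoint(kept).convex_hull
    if isinstance(hull, Polygon) and hull.area > 0:
        hull = orient(hull, sign=1.0)
        verts = np.asarray(hull.exterior.coords)[:-1]
        return MCPolygon(verts, float(hull.area), retain, n, n_used)
    return MCPolygon(np.unique(kept, axis=0), 0.0, retain, n, n_used,
                     degenerate=True)


def element_diversity_scores(coords: np.ndarray, song_ids,
                             retain: float = 0.95) -> dict:
    """Per-song 95% MCP area of that song's elements in a 2-D embedding.

    ``coords`` are the first two embedding axes for every element, aligned
    with ``song_ids``. Songs whose elements cannot span a polygon (fewer than
    three, or collinear/coincident) score 0; the count of such degenerate
    songs is reported via a warning.
    """
    coords = np.asarray(coords, dtype=float)[:, :2]
    song_ids = np.asarray(song_ids)
    if len(coords) != len(song_ids):
        raise ValueError("coords and song_ids must align")
    out = {}
    n_degenerate = 0
    for sid in pd_unique(song_ids):
        poly = mcp(coords[song_ids == sid], retain)
        out[sid] = poly.area
        n_degenerate += poly.degenerate
    if n_degenerate:
        warnings.warn(f"{n_degenerate} songs with degenerate element polygons (area 0)")
    return out


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def acoustic_area_by_sex(coords: np.ndarray, sexes, retain: float = 0.95
                         ) -> tuple[MCPolygon, MCPolygon]:
    """Male and female 95% MCPs of one population's songs in the embedding."""
    sexes = np.asarray(sexes)
    male, female = coords[sexes == "male"], coords[sexes == "female"]
    if len(male) == 0 or len(female) == 0:
        raise ValueError("both sexes must be present")
    return mcp(male, retain), mcp(female, retain)


def _zscore_axes(points: np.ndarray, pooled: np.ndarray) -> np.ndarray:
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (points - mean) / sd


def dimorphism_metrics(male_points: np.ndarray, female_points: np.ndarray,
                       pooled_points: np.ndarray | None = None,
                       retain: float = 0.95,
                       denominator: str = "union") -> tuple[float, float, float]:
    """The three male-female acoustic-area dimorphism metrics.

    - ``overlap_prop``: area of the intersection of the sex MCPs divided by
      the combined ("entire") acoustic area;
    - ``centroid_distance``: Euclidean distance between the per-sex centroids
      after z-scoring each axis on the pooled points (both sexes), making
      distances comparable across populations;
    - ``area_size_difference``: ``|area_m - area_f|`` over the combined area.

    ``denominator`` selects the reading of the combined area: ``"union"``
    (area of the union of the two sex polygons; guarantees overlap in [0, 1])
    or ``"pooled_mcp"`` (MCP of the pooled points). If both polygons are
    degenerate all metrics are 0; if exactly one is, overlap is 0 and the
    size difference 1.
    """
    m = np.asarray(male_points, dtype=float)
    f = np.asarray(female_points, dtype=float)
    if len(m) == 0 or len(f) == 0:
        raise ValueError("both point sets must be non-empty")
    pooled = np.vstack([m, f]) if pooled_points is None else np.asarray(pooled_points)

    pm, pf = mcp(m, retain), mcp(f, retain)
    mz = _zscore_axes(m, pooled)
    fz = _zscore_axes(f, pooled)
    centroid_distance = float(np.linalg.norm(mz.mean(axis=0) - fz.mean(axis=0)))

    if pm.degenerate and pf.degenerate:
        return 0.0, 0.0, 0.0
    if pm.degenerate or pf.degenerate:
        return 0.0, centroid_distance, 1.0

    gm, gf = pm.shapely, pf.shapely
    inter = gm.intersection(gf).area
    if denominator == "union":
        total = gm.union(gf).area
    elif denominator == "pooled_mcp":
        total = mcp(pooled, retain).shapely.area
    else:
        raise ValueError("denominator must be 'union' or 'pooled_mcp'")
    if total <= 0:
        return 0.0, centroid_distance, 0.0
    overlap = inter / total
    size_diff = abs(gm.area - gf.area) / total
    return float(overlap), centroid_distance, float(size_diff)


@dataclass
class DimorphismResult:
    """Averaged dimorphism metrics with per-iteration resampling provenance."""

    population: str
    overlap_prop: float
    centroid_distance: float
    area_size_difference: float
    n_iterations: int
    per_iteration: np.ndarray  # (n_iterations, 3)
    seed: int
    n_male: int = 0
    n_female: int = 0
    extra: dict = field(default_factory=dict)


def balanced_subsample_dimorphism(male_points, female_points,
                                  pooled_points=None, n_iter: int = 100,
                                  seed: int = 0, retain: float = 0.95,
                                  population: str = "",
                                  denominator: str = "union") -> DimorphismResult:
    """Average the dimorphism metrics over balanced random subsamples.

    Each iteration subsamples the larger sex without replacement down to the
    smaller sex's sample size and recomputes the three metrics on the fixed
    embedding; the reported metrics are the arithmetic means. Child seeds are
    derived from the master seed by iteration counter, so equal seeds give
    bit-identical results, and with equal sex sample sizes every iteration
    uses the full data (per-iteration variance exactly 0).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    m = np.asarray(male_points, dtype=float)
    f = np.asarray(female_points, dtype=float)
    pooled = np.vstack([m, f]) if pooled_points is None else np.asarray(pooled_points)
    n_small = min(len(m), len(f))
    per_iter = np.empty((n_iter, 3))
    for i in range(n_iter):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        mi = m if len(m) == n_small else m[rng.choice(len(m), n_small, replace=False)]
        fi = f if len(f) == n_small else f[rng.choice(len(f), n_small, replace=False)]
        per_iter[i] = dimorphism_metrics(mi, fi, pooled, retain, denominator)
    means = per_iter.mean(axis=0)
    return DimorphismResult(
        population=population,
        overlap_prop=float(means[0]),
        centroid_distance=float(means[1]),
        area_size_difference=float(means[2]),
        n_iterations=n_iter,
        per_iteration=per_iter,
        seed=seed,
        n_male=len(m),
        n_female=len(f),
    )
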