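"""Bounded Voronoi tessellation of test-location grids.

Irregular perimetric grids are visualized as Voronoi tiles: every point
inside a tile is closer to the tile's generating test location than to
any other.  Cells are built by intersecting half-planes against a convex
clip boundary, which keeps edge tiles finite and handles degenerate
(collinear) grids without special cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point, Polygon

from .grids import Grid

__all__ = [
    "Tessellation",
    "TessellationError",
    "default_clip_boundary",
    "voronoi_tessellate",
    "adjacency_from_tessellation",
    "neighbors_map",
]

_EDGE_TOL = 1e-9
_AREA_RTOL = 1e-6


class TessellationError(ValueError):
    """Invalid tessellation input or failed geometric invariant."""


@dataclass
class Tessellation:
    """A bounded Voronoi diagram: one convex tile per generating point."""

    points: np.ndarray  #: (n, 2) generators, degrees
    polygons: list[np.ndarray]  #: per-location vertex rings, degrees
    clip_boundary: np.ndarray  #: convex clip polygon vertices
    cells: list[Polygon] = field(repr=False, default_factory=list)

    def __len__(self) -> int:
        return len(self.polygons)

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.cells])


def default_clip_boundary(points: np.ndarray) -> Polygon:
    """Convex hull of the points dilated by half the median
    nearest-neighbor distance, so that edge locations get finite tiles."""
    pts = np.asarray(points, dtype=float)
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    pad = float(np.median(dist[:, 1])) / 2.0
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    # mitre join / square cap keep the dilation a convex polygon even for
    # degenerate (collinear or single-point) hulls
    return hull.buffer(pad, join_style=2, cap_style=3)


def _halfplane(pi: np.ndarray, pj: np.ndarray, reach: float) -> Polygon:
    """Polygon covering (within `reach`) the points closer to pi than pj."""
    mid = (pi + pj) / 2.0
    d = pj - pi
    n = d / np.linalg.norm(d)
    t = np.array([-n[1], n[0]])
    a = mid + t * reach
    b = mid - t * reach
    return Polygon([a, b, b - n * 2 * reach, a - n * 2 * reach])


def voronoi_tessellate(
    grid: Grid | np.ndarray, clip_boundary=None
) -> Tessellation:
    """Tessellate a grid (or (n, 2) point array) into bounded Voronoi tiles.

    Parameters
    ----------
    grid
        Grid or point array with >= 2 distinct locations.
    clip_boundary
        Convex polygon (shapely Polygon or (k, 2) vertex array) containing
        all locations.  Defaults to the dilated convex hull of the points.

    Raises
    ------
    TessellationError
        If fewer than 2 points, a point lies outside the boundary, or the
        boundary is not convex.
    """
    pts = grid.coords() if isinstance(grid, Grid) else np.asarray(grid, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise TessellationError("need >= 2 points with (x, y) coordinates")
    if clip_boundary is None:
        boundary = default_clip_boundary(pts)
    elif isinstance(clip_boundary, Polygon):
        boundary = clip_boundary
    else:
        boundary = Polygon(np.asarray(clip_boundary, dtype=float))
    if not boundary.is_valid or boundary.area <= 0:
        raise TessellationError("clip boundary is not a valid polygon")
    if boundary.convex_hull.area > boundary.area * (1 + 1e-9):
        raise TessellationError("clip boundary must be convex")
    for k, p in enumerate(pts):
        if not boundary.covers(Point(p)):
            raise TessellationError(
                f"location {k} at ({p[0]}, {p[1]}) lies outside the clip "
                "boundary"
            )

    minx, miny, maxx, maxy = boundary.bounds
    reach = 4.0 * max(maxx - minx, maxy - miny, 1.0)
    cells: list[Polygon] = []
    for i, pi in enumerate(pts):
        cell = boundary
        for j, pj in enumerate(pts):
            if j == i:
                continue
            cell = cell.intersection(_halfplane(pi, pj, reach))
            if cell.is_empty:
                break
        if cell.is_empty or not cell.contains(Point(pi)):
            raise TessellationError(
                f"generator {i} does not lie inside its own cell "
                "(duplicate points?)"
            )
        cells.append(cell)

    total = sum(c.area for c in cells)
    if abs(total - boundary.area) > _AREA_RTOL * boundary.area:
        raise TessellationError(
            f"tile areas sum to {total}, boundary area {boundary.area}"
        )
    polygons = [np.asarray(c.exterior.coords)[:-1] for c in cells]
    return Tessellation(
        points=pts,
        polygons=polygons,
        clip_boundary=np.asarray(boundary.exterior.coords)[:-1],
        cells=cells,
    )


def adjacency_from_tessellation(tess: Tessellation) -> set[tuple[int, int]]:
    """Symmetric set of index pairs whose tiles share a boundary segment
    (length > 1e-9; point contacts do not count)."""
    edges: set[tuple[int, int]] = set()
    n = len(tess.cells)
    for i in range(n):
        for j in range(i + 1, n):
            shared = tess.cells[i].intersection(tess.cells[j])
            if shared.length > _EDGE_TOL:
                edges.add((i, j))
                edges.add((j, i))
    return edges


def neighbors_map(
    edges: set[tuple[int, int]], n: int
) -> list[set[int]]:
    """Per-location neighbor sets from a symmetric edge set."""
    nbrs: list[set[int]] = [set() for _ in range(n)]
    for i, j in edges:
        nbrs[i].add(j)
    return nbrs
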