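"""Section geometry: neighbor network, boundary polygon, tessellation.

The neighbor relation ``i ~ j`` between fibers is derived from the Delaunay
triangulation of the fiber centroids, pruned to remove spurious long edges
(which otherwise bridge concavities of the section outline).  The section
boundary is an alpha shape of the centroids with a convex-hull fallback, and
the tessellation is the Voronoi diagram of the centroids clipped to that
boundary — the per-fiber "cells" shown in typical section plots.

All constructions are scale-free: pruning thresholds and the default alpha
are defined relative to the observed edge-length distribution, so the edge
set is invariant under translation, rotation and uniform scaling of the
input coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPoint, Polygon
from shapely.geometry.polygon import orient
from shapely.ops import unary_union, voronoi_diagram
from shapely.strtree import STRtree

from .section_io import FiberSection

__all__ = [
    "GeometryError",
    "PruneConfig",
    "NeighborNetwork",
    "SectionGeometry",
    "delaunay_network",
    "boundary_polygon",
    "tessellation",
    "export_network_csv",
]

logger = logging.getLogger("myofibspat")


class GeometryError(Exception):
    """Degenerate point configuration or inconsistent geometry input."""


@dataclass(frozen=True)
class PruneConfig:
    """Rules removing spurious edges from the raw Delaunay triangulation.

    ``length_factor``: drop edges longer than Q3 + length_factor * IQR of the
    edge-length distribution (None disables).  ``clip_to_boundary``: drop
    edges whose midpoint falls outside the section boundary polygon.
    ``alpha``: concavity parameter forwarded to :func:`boundary_polygon`
    (None = automatic).
    """

    length_factor: float | None = 1.5
    clip_to_boundary: bool = True
    alpha: float | None = None


@dataclass(frozen=True)
class NeighborNetwork:
    """Undirected neighbor graph over the fibers of one section."""

    n: int
    edges: np.ndarray  # (m, 2) int array, i < j, lexicographically sorted
    lengths: np.ndarray  # (m,) Euclidean edge lengths

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        lengths = np.asarray(self.lengths, dtype=np.float64).reshape(-1)
        if edges.size:
            if (edges[:, 0] >= edges[:, 1]).any():
                raise GeometryError("edges must be stored with i < j (no self-loops)")
            if edges.min() < 0 or edges.max() >= self.n:
                raise GeometryError("edge endpoint out of range")
            if len(np.unique(edges[:, 0] * self.n + edges[:, 1])) != len(edges):
                raise GeometryError("duplicate edges")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "lengths", lengths)

    @property
    def m(self) -> int:
        return len(self.edges)

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        if self.m:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def adjacency(self) -> csr_array:
        """Symmetric sparse 0/1 adjacency matrix."""
        if self.m == 0:
            return csr_array((self.n, self.n))
        i = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        j = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        return csr_array((np.ones(2 * self.m), (i, j)), shape=(self.n, self.n))

    def neighbor_lists(self) -> list[np.ndarray]:
        adj = self.adjacency()
        return [adj.indices[adj.indptr[i]: adj.indptr[i + 1]] for i in range(self.n)]

    def n_components(self) -> int:
        return int(connected_components(self.adjacency(), directed=False)[0])


@dataclass(frozen=True)
class SectionGeometry:
    """Boundary polygon, per-fiber Voronoi cells and the triangulation."""

    boundary: Polygon
    cells: tuple
    triangulation: np.ndarray  # (t, 3) simplex indices


def _delaunay(coords: np.ndarray) -> Delaunay:
    try:
        tri = Delaunay(coords)
    except QhullError as exc:
        raise GeometryError(f"degenerate point configuration: {exc}") from exc
    if tri.simplices.size == 0:
        raise GeometryError("points are collinear: no triangulation exists")
    return tri


def _delaunay_edges(tri: Delaunay) -> np.ndarray:
    s = tri.simplices
    e = np.concatenate([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def delaunay_network(section: FiberSection, prune: PruneConfig | None = None) -> NeighborNetwork:
    """Build the neighbor network from the pruned Delaunay triangulation.

    With ``prune=None`` the default :class:`PruneConfig` applies; pass
    ``PruneConfig(length_factor=None, clip_to_boundary=False)`` for the raw
    triangulation.
    """
    if prune is None:
        prune = PruneConfig()
    coords = section.coords
    tri = _delaunay(coords)
    edges = _delaunay_edges(tri)
    lengths = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)

    keep = np.ones(len(edges), dtype=bool)
    if prune.length_factor is not None and len(edges):
        q1, q3 = np.percentile(lengths, [25, 75])
        thr = q3 + prune.length_factor * (q3 - q1)
        keep &= lengths <= thr
    if prune.clip_to_boundary:
        boundary = boundary_polygon(section, alpha=prune.alpha)
        mids = (coords[edges[:, 0]] + coords[edges[:, 1]]) / 2.0
        # perimeter-edge midpoints lie exactly on the boundary; a relative
        # tolerance keeps the rule invariant to rotation/scaling round-off
        tol = 1e-9 * float(np.median(lengths)) if len(lengths) else 0.0
        inside = shapely.dwithin(shapely.points(mids), boundary, tol)
        keep &= inside
    edges, lengths = edges[keep], lengths[keep]

    network = NeighborNetwork(n=section.n, edges=edges, lengths=lengths)
    ncomp = network.n_components()
    if ncomp > 1:
        warnings.warn(
            f"neighbor network is disconnected after pruning ({ncomp} components)",
            stacklevel=2,
        )
    logger.info("neighbor network: n=%d, m=%d (pruned %d of %d Delaunay edges)",
                section.n, network.m, int((~keep).sum()), len(keep))
    return network


def _circumradii(coords: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = coords[simplices[:, 0]]
    b = coords[simplices[:, 1]]
    c = coords[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    area = 0.5 * np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )
    with np.errstate(divide="ignore"):
        return np.where(area > 0, la * lb * lc / (4.0 * area), np.inf)


def _convex_hull(coords: np.ndarray) -> Polygon:
    hull = MultiPoint(coords).convex_hull
    if not isinstance(hull, Polygon):
        raise GeometryError("points are collinear: no polygonal hull exists")
    return orient(hull)


def boundary_polygon(section: FiberSection, alpha: float | None = None) -> Polygon:
    """Alpha-shape boundary of the section (counter-clockwise simple polygon).

    ``alpha`` is the circumradius threshold of the alpha shape: Delaunay
    triangles with circumradius below ``alpha`` are kept and their union is
    the section outline.  The default is twice the median Delaunay edge
    length, which tracks the fiber packing density.  ``alpha=inf`` (or any
    alpha so large no triangle is removed) yields the convex hull; an alpha
    so small the shape fragments or drops centroids falls back to the convex
    hull with a warning.
    """
    coords = section.coords
    tri = _delaunay(coords)
    if alpha is not None and np.isinf(alpha):
        return _convex_hull(coords)
    if alpha is None:
        edges = _delaunay_edges(tri)
        lengths = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
        alpha = 2.0 * float(np.median(lengths))
    radii = _circumradii(coords, tri.simplices)
    kept = tri.simplices[radii < alpha]
    if len(kept) == 0:
        warnings.warn("alpha too small: no triangles kept; using convex hull", stacklevel=2)
        return _convex_hull(coords)
    shape = unary_union([Polygon(coords[s]) for s in kept])
    ok = isinstance(shape, Polygon) and shapely.covers(shape, shapely.points(coords)).all()
    if not ok:
        warnings.warn(
            "alpha shape fragments or drops centroids; falling back to convex hull",
            stacklevel=2,
        )
        return _convex_hull(coords)
    return orient(shape)


def tessellation(section: FiberSection, boundary: Polygon) -> SectionGeometry:
    """Voronoi cells of the fiber centroids clipped to the section boundary.

    Each fiber's cell covers its centroid and the cells tile the boundary
    polygon (areas conserved to 0.5%).
    """
    coords = section.coords
    pts = shapely.points(coords)
    inside = shapely.covers(boundary, pts)
    if not inside.all():
        bad = np.flatnonzero(~inside).tolist()
        raise GeometryError(f"centroid(s) outside boundary polygon: fiber_id {bad}")

    raw = voronoi_diagram(MultiPoint(coords), envelope=boundary.buffer(1.0))
    polys = list(raw.geoms)
    tree = STRtree(polys)
    cell_idx, pt_idx = tree.query(pts, predicate="within")  # (2, k) pairs: input, tree
    # query returns (input_index_array, tree_index_array)
    owner = np.full(section.n, -1, dtype=np.int64)
    for p, c in zip(cell_idx, pt_idx):
        owner[p] = c
    if (owner < 0).any():
        # a centroid sitting exactly on a Voronoi edge: resolve by distance
        for i in np.flatnonzero(owner < 0):
            d = [polys[k].distance(pts[i]) for k in range(len(polys))]
            owner[i] = int(np.argmin(d))
    cells = []
    for i in range(section.n):
        cell = polys[owner[i]].intersection(boundary)
        if not isinstance(cell, Polygon) or not shapely.covers(cell.buffer(1e-9), pts[i]):
            raise GeometryError(f"could not form a valid cell for fiber_id {i}")
        cells.append(cell)
    total = sum(c.area for c in cells)
    if not (0.995 <= total / boundary.area <= 1.005):
        raise GeometryError(
            f"tessellation does not tile the boundary: cell area {total:.6g} "
            f"vs polygon area {boundary.area:.6g}"
        )
    tri = _delaunay(coords)
    return SectionGeometry(boundary=boundary, cells=tuple(cells), triangulation=tri.simplices.copy())


def export_network_csv(network: NeighborNetwork, path: str | Path) -> Path:
    """Write the edge list as a CSV of (i, j, length)."""
    import pandas as pd

    path = Path(path)
    pd.DataFrame(
        {"i": network.edges[:, 0], "j": network.edges[:, 1], "length": network.lengths}
    ).to_csv(path, index=False)
    return path
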