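"""Exact 2D polygon primitives for quadrilateral state-space cells.

Every cell of a state-space mesh is a quadrilateral whose four vertices are
stored in counter-clockwise (CCW) order.  This module provides the small set
of geometric operations the rest of the package relies on: signed area,
simplicity/convexity classification, closed point-membership tests and
uniform sampling of points inside a cell.  All computations are done in
double precision; orientation predicates use a relative epsilon of 1e-12 on
coordinates normalised by the polygon's extent.

Conventions
-----------
* Boundary points count as *inside* (closed cells).  A point falling exactly
  on an edge shared by two cells therefore belongs to both; callers resolve
  the double count by a first-match-wins rule in (strip, cell) search order.
* Concave simple quadrilaterals are handled by splitting along the single
  diagonal that lies inside the polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "InvalidPolygonError",
    "DegenerateCellError",
    "ComplexCellError",
    "QuadCell",
    "polygon_area",
    "classify_quad",
    "contains",
    "contains_many",
    "triangulate_quad",
    "sample_uniform",
]

#: relative tolerance for orientation predicates on normalised coordinates
EPS = 1e-12


class GeometryError(ValueError):
    """Base class for geometry failures."""


class InvalidPolygonError(GeometryError):
    """Fewer than three vertices, or non-finite coordinates."""


class DegenerateCellError(GeometryError):
    """Duplicate vertices or (effectively) zero area."""


class ComplexCellError(GeometryError):
    """Self-intersecting quadrilateral where a simple one is required."""


def _as_verts(vertices, min_n: int = 3) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < min_n:
        raise InvalidPolygonError(
            f"expected >= {min_n} 2D vertices, got shape {v.shape}"
        )
    if not np.all(np.isfinite(v)):
        raise InvalidPolygonError("non-finite vertex coordinates")
    return v


def polygon_area(vertices) -> float:
    """Signed shoelace area of a polygon; positive iff vertices are CCW."""
    v = _as_verts(vertices)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _scale(v: np.ndarray) -> float:
    """Characteristic length used to normalise orientation predicates."""
    ext = v.max(axis=0) - v.min(axis=0)
    return max(float(ext[0]), float(ext[1]), 1e-300)


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _segments_properly_intersect(p1, p2, q1, q2, tol: float) -> bool:
    """True iff open segments (p1,p2) and (q1,q2) cross each other."""
    d1 = _cross(q1, q2, p1)
    d2 = _cross(q1, q2, p2)
    d3 = _cross(p1, p2, q1)
    d4 = _cross(p1, p2, q2)
    return (
        ((d1 > tol and d2 < -tol) or (d1 < -tol and d2 > tol))
        and ((d3 > tol and d4 < -tol) or (d3 < -tol and d4 > tol))
    )


def classify_quad(vertices) -> str:
    """Classify a quadrilateral as convex_simple, concave_simple or complex.

    A quadrilateral is *complex* when its two pairs of non-adjacent edges
    intersect; *concave* when it is simple but one interior angle exceeds
    180 degrees.  Duplicate vertices raise :class:`DegenerateCellError`.
    """
    v = _as_verts(vertices, min_n=4)
    if v.shape[0] != 4:
        raise InvalidPolygonError("classify_quad expects exactly 4 vertices")
    s = _scale(v)
    for i in range(4):
        for j in range(i + 1, 4):
            if np.all(np.abs(v[i] - v[j]) <= EPS * s):
                raise DegenerateCellError("duplicate vertices in quadrilateral")
    tol = EPS * s * s
    # non-adjacent edge pairs of a quad: (0-1, 2-3) and (1-2, 3-0)
    if _segments_properly_intersect(v[0], v[1], v[2], v[3], tol) or (
        _segments_properly_intersect(v[1], v[2], v[3], v[0], tol)
    ):
        return "complex"
    crosses = np.array(
        [_cross(v[i], v[(i + 1) % 4], v[(i + 2) % 4]) for i in range(4)]
    )
    if np.any(crosses > tol) and np.any(crosses < -tol):
        return "concave_simple"
    return "convex_simple"


def triangulate_quad(vertices) -> tuple[np.ndarray, np.ndarray]:
    """Split a simple quadrilateral into two triangles along an interior diagonal.

    For a convex quad either diagonal works; for a concave one exactly one
    diagonal lies inside the polygon, namely the one incident to the reflex
    vertex.
    """
    v = _as_verts(vertices, min_n=4)
    kind = classify_quad(v)
    if kind == "complex":
        raise ComplexCellError("cannot triangulate a self-intersecting quad")
    if kind == "convex_simple":
        return v[[0, 1, 2]], v[[0, 2, 3]]
    crosses = np.array(
        [_cross(v[i], v[(i + 1) % 4], v[(i + 2) % 4]) for i in range(4)]
    )
    # vertex v[(i+1)%4] is reflex where the cross product flips against the
    # dominant orientation sign
    majority = 1.0 if np.sum(crosses > 0) >= np.sum(crosses < 0) else -1.0
    reflex = (int(np.argmin(majority * crosses)) + 1) % 4
    idx = [(reflex + k) % 4 for k in range(4)]
    # diagonal from the reflex vertex to the opposite vertex is interior
    return v[[idx[0], idx[1], idx[2]]], v[[idx[0], idx[2], idx[3]]]


def _points_in_convex(verts: np.ndarray, pts: np.ndarray, tol: float) -> np.ndarray:
    """Half-plane test of pts against a convex CCW polygon (closed boundary)."""
    inside = np.ones(len(pts), dtype=bool)
    n = len(verts)
    for i in range(n):
        a = verts[i]
        b = verts[(i + 1) % n]
        e = b - a
        # inward normal of a CCW edge is (-e_y, e_x); positive dot => inside
        d = (pts[:, 0] - a[0]) * (-e[1]) + (pts[:, 1] - a[1]) * e[0]
        inside &= d >= -tol
    return inside


def _ccw(verts: np.ndarray) -> np.ndarray:
    return verts if polygon_area(verts) >= 0 else verts[::-1]


def contains_many(vertices, points) -> np.ndarray:
    """Vectorised closed-membership test of many points against one quad."""
    v = _as_verts(vertices, min_n=4)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    s = _scale(v)
    tol = EPS * s * s
    kind = classify_quad(v)
    if kind == "complex":
        raise ComplexCellError("membership test unsupported for complex cells")
    if kind == "convex_simple":
        return _points_in_convex(_ccw(v), pts, tol)
    t1, t2 = triangulate_quad(v)
    return _points_in_convex(_ccw(t1), pts, tol) | _points_in_convex(_ccw(t2), pts, tol)


def contains(vertices, point) -> bool:
    """Closed point-in-quadrilateral test (boundary counts as inside)."""
    return bool(contains_many(vertices, np.asarray(point, dtype=float)[None, :])[0])


def _sample_triangle(tri: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    r1 = rng.random(n)
    r2 = rng.random(n)
    flip = r1 + r2 > 1.0
    r1[flip] = 1.0 - r1[flip]
    r2[flip] = 1.0 - r2[flip]
    return tri[0] + np.outer(r1, tri[1] - tri[0]) + np.outer(r2, tri[2] - tri[0])


def sample_uniform(vertices, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` points uniformly over the area of a simple quadrilateral.

    The quad is split into two triangles; each point is assigned to a
    triangle with probability proportional to its area and placed uniformly
    inside it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    v = _as_verts(vertices, min_n=4)
    if abs(polygon_area(v)) <= EPS * _scale(v) ** 2:
        raise DegenerateCellError("cannot sample a zero-area cell")
    t1, t2 = triangulate_quad(v)
    a1, a2 = abs(polygon_area(t1)), abs(polygon_area(t2))
    n1 = int(rng.binomial(n, a1 / (a1 + a2)))
    parts = []
    if n1 > 0:
        parts.append(_sample_triangle(t1, n1, rng))
    if n - n1 > 0:
        parts.append(_sample_triangle(t2, n - n1, rng))
    return np.concatenate(parts, axis=0)


@dataclass
class QuadCell:
    """One quadrilateral mesh cell.

    Vertices are stored CCW; ``strip_index``/``cell_index`` are the grid
    coordinates (i, j).  ``area`` is the unsigned area.
    """

    vertices: np.ndarray
    strip_index: int
    cell_index: int
    area: float = field(init=False)

    def __post_init__(self):
        v = _as_verts(self.vertices, min_n=4)
        if v.shape[0] != 4:
            raise InvalidPolygonError("QuadCell requires exactly 4 vertices")
        if polygon_area(v) < 0:
            v = v[::-1].copy()
        self.vertices = v
        self.area = abs(polygon_area(v))

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        return (float(lo[0]), float(lo[1]), float(hi[0]), float(hi[1]))

    def classify(self) -> str:
        return classify_quad(self.vertices)

    def contains(self, point) -> bool:
        return contains(self.vertices, point)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return sample_uniform(self.vertices, n, rng)
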