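"""Planar geometry for vowel-space areas.

All routines work in the (F2, F1) plane with x = F2 and y = F1, the
plane in which vowel charts are drawn. Areas are in Hz².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError


@dataclass(frozen=True)
class HullResult:
    """Convex hull of a point cloud.

    ``vertices`` are a counter-clockwise subset of the input points with
    strictly collinear boundary points removed; ``area`` is the enclosed
    area.
    """

    vertices: np.ndarray  # (k, 2), counter-clockwise
    area: float
    n_input: int


def _as_points(points, min_points: int) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array of points, got shape {pts.shape}")
    if len(pts) < min_points:
        raise DegenerateGeometryError(
            f"need at least {min_points} points, got {len(pts)}"
        )
    return pts


def shoelace_signed(vertices: np.ndarray) -> float:
    """Signed shoelace sum / 2; positive for counter-clockwise order."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(vertices, *, check_simple: bool = False) -> float | tuple[float, bool]:
    """Absolute polygon area via the shoelace formula.

    Invariant to cyclic rotation of the vertex list and to traversal
    direction. With ``check_simple=True`` also returns whether any two
    non-adjacent edges properly intersect (a self-intersecting outline
    makes the shoelace area geometrically meaningless, so callers warn).
    """
    verts = _as_points(vertices, 3)
    area = abs(shoelace_signed(verts))
    if not check_simple:
        return area
    return area, _self_intersects(verts)


def _self_intersects(verts: np.ndarray) -> bool:
    n = len(verts)
    edges = [(verts[i], verts[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue  # adjacent edges share a vertex
            if _segments_properly_intersect(*edges[i], *edges[j]):
                return True
    return False


def _segments_properly_intersect(p1, p2, q1, q2) -> bool:
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1, d2 = cross(q1, q2, p1), cross(q1, q2, p2)
    d3, d4 = cross(p1, p2, q1), cross(p1, p2, q2)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)) and all(
        d != 0 for d in (d1, d2, d3, d4)
    )


def convex_hull(points) -> HullResult:
    """Convex hull by Andrew's monotone chain.

    Returns vertices in counter-clockwise order with strictly collinear
    boundary points excluded, so the vertex set is the canonical minimal
    one. Duplicated input coordinates never affect the hull.

    Raises
    ------
    DegenerateGeometryError
        If fewer than 3 distinct points remain or all points are
        collinear.
    """
    pts = _as_points(points, 3)
    unique = np.unique(pts, axis=0)
    if len(unique) < 3:
        raise DegenerateGeometryError("fewer than 3 distinct points")
    # lexicographic sort by (x, y)
    order = np.lexsort((unique[:, 1], unique[:, 0]))
    p = unique[order]

    def half(points_iter):
        chain: list[np.ndarray] = []
        for pt in points_iter:
            while len(chain) >= 2 and _cross(chain[-2], chain[-1], pt) <= 0:
                chain.pop()
            chain.append(pt)
        return chain

    lower = half(p)
    upper = half(p[::-1])
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:
        raise DegenerateGeometryError("all points are collinear")
    vertices = np.array(hull)
    return HullResult(vertices=vertices, area=abs(shoelace_signed(vertices)), n_input=len(pts))


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def brute_force_hull_vertices(points) -> np.ndarray:
    """O(n³) supporting-line hull, for use as an independent oracle.

    A directed pair (p, q) of distinct points is a hull edge iff every
    other point lies strictly to its left or on the segment between
    them; collecting edge endpoints and ordering them by angle about the
    centroid yields the counter-clockwise vertex list. Collinear
    boundary points are excluded to match :func:`convex_hull`'s
    canonical form. Intended for small n only.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    n = len(pts)
    if n < 3:
        raise DegenerateGeometryError("fewer than 3 distinct points")
    on_hull = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            u = pts[j] - pts[i]
            w = pts - pts[i]
            d = u[0] * w[:, 1] - u[1] * w[:, 0]
            if np.all(d >= 0):
                # all points on/left of i->j: both are hull points, but
                # drop any k strictly between i and j on the edge line
                on_hull[i] = on_hull[j] = True
    verts = pts[on_hull]
    if len(verts) < 3:
        raise DegenerateGeometryError("all points are collinear")
    centroid = verts.mean(axis=0)
    angles = np.arctan2(verts[:, 1] - centroid[1], verts[:, 0] - centroid[0])
    verts = verts[np.argsort(angles)]
    # remove collinear triples to obtain the minimal vertex set
    keep = []
    m = len(verts)
    for k in range(m):
        if _cross(verts[k - 1], verts[k], verts[(k + 1) % m]) != 0:
            keep.append(k)
    return verts[keep]
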