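"""Convex hull, rotating-calipers ferret diameters, minimum-area rectangle.

All operations work on pixel centers expressed as (row, col) coordinates.
Internally points are handled as (x, y) = (col, row); hull vertices are
stored counterclockwise in that frame.  An optional pixel-extent helper
expands each point to its four half-pixel corners before hull construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Hull:
    """Convex hull vertices, counterclockwise, no three collinear."""

    vertices: np.ndarray  # (k, 2) float array of (row, col)

    def __len__(self) -> int:
        return int(self.vertices.shape[0])


@dataclass(frozen=True)
class RectangleFit:
    """Minimum-area oriented bounding rectangle.

    ``angle`` is the orientation of the long side in degrees from the
    column axis, in [0, 180).
    """

    center: tuple[float, float]  # (row, col)
    length: float  # longer side
    width: float  # shorter side
    angle: float

    @property
    def area(self) -> float:
        return self.length * self.width


def _cross(o: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return float((a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0]))


def convex_hull(points) -> Hull:
    """Andrew monotone-chain hull of a set of (row, col) points.

    Degenerate inputs return a degenerate hull: a single vertex for one
    distinct point, two endpoints for a collinear set.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("empty point set")
    xy = np.unique(pts[:, ::-1], axis=0)  # (x, y), sorted lexicographically
    if xy.shape[0] == 1:
        return Hull(vertices=xy[:, ::-1].copy())

    def _chain(seq):
        out: list[np.ndarray] = []
        for p in seq:
            while len(out) >= 2 and _cross(out[-2], out[-1], p) <= 0:
                out.pop()
            out.append(p)
        return out

    lower = _chain(xy)
    upper = _chain(xy[::-1])
    verts = np.array(lower[:-1] + upper[:-1])
    if verts.shape[0] == 0:  # fully collinear: keep the two endpoints
        verts = np.array([xy[0], xy[-1]])
    return Hull(vertices=verts[:, ::-1])


def with_pixel_extent(hull: Hull) -> Hull:
    """Re-hull the four half-pixel corners of every hull vertex.

    Models each pixel as a unit square instead of a point; widens every
    ferret/rectangle measure by about one pixel.
    """
    v = hull.vertices
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    corners = (v[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    return convex_hull(corners)


def ferret_diameters(hull: Hull) -> tuple[float, float]:
    """(min ferret, max ferret) of a convex hull via rotating calipers.

    The max ferret is the largest distance over antipodal vertex pairs; the
    min ferret is the smallest width across all edge-aligned supporting
    lines.  Degenerate hulls: a point gives (0, 0); a segment gives
    (0, segment length).
    """
    v = hull.vertices[:, ::-1]  # (x, y), counterclockwise
    n = v.shape[0]
    if n == 1:
        return 0.0, 0.0
    if n == 2:
        return 0.0, float(np.hypot(*(v[1] - v[0])))

    def area2(i: int, i1: int, j: int) -> float:
        return _cross(v[i], v[i1], v[j])

    max_sq = 0.0
    min_width = math.inf
    j = 1
    for i in range(n):
        i1 = (i + 1) % n
        guard = 0
        while area2(i, i1, (j + 1) % n) > area2(i, i1, j):
            j = (j + 1) % n
            guard += 1
            if guard > n:  # pragma: no cover - strictly convex hulls terminate
                break
        edge_len = float(np.hypot(*(v[i1] - v[i])))
        min_width = min(min_width, area2(i, i1, j) / edge_len)
        for k in (j, (j + 1) % n):
            for p in (i, i1):
                d = v[k] - v[p]
                max_sq = max(max_sq, float(d @ d))
    return float(min_width), math.sqrt(max_sq)


def min_area_rectangle(hull: Hull) -> RectangleFit:
    """Smallest-area oriented rectangle containing the hull.

    The optimal rectangle has one side collinear with a hull edge; every
    edge orientation is scanned and ties are broken by the smaller angle.
    """
    v = hull.vertices[:, ::-1]  # (x, y)
    n = v.shape[0]
    if n == 1:
        return RectangleFit(center=(float(hull.vertices[0, 0]), float(hull.vertices[0, 1])),
                            length=0.0, width=0.0, angle=0.0)
    if n == 2:
        d = v[1] - v[0]
        mid = (v[0] + v[1]) / 2.0
        return RectangleFit(center=(float(mid[1]), float(mid[0])),
                            length=float(np.hypot(*d)), width=0.0,
                            angle=_angle_deg(d))

    best = None
    for i in range(n):
        e = v[(i + 1) % n] - v[i]
        u = e / np.hypot(*e)
        w = np.array([-u[1], u[0]])
        pu = v @ u
        pw = v @ w
        du = float(pu.max() - pu.min())
        dw = float(pw.max() - pw.min())
        area = du * dw
        if du >= dw:
            length, width, axis = du, dw, u
        else:
            length, width, axis = dw, du, w
        angle = _angle_deg(axis)
        cu = (pu.max() + pu.min()) / 2.0
        cw = (pw.max() + pw.min()) / 2.0
        center_xy = cu * u + cw * w
        cand = (area, angle, length, width, (float(center_xy[1]), float(center_xy[0])))
        if best is None or area < best[0] - 1e-12 * max(1.0, best[0]) or (
            abs(area - best[0]) <= 1e-12 * max(1.0, best[0]) and angle < best[1]
        ):
            best = cand
    area, angle, length, width, center = best
    return RectangleFit(center=center, length=length, width=width, angle=angle)


def _angle_deg(direction: np.ndarray) -> float:
    """Orientation of an (x, y) direction in degrees, reduced to [0, 180)."""
    ang = math.degrees(math.atan2(float(direction[1]), float(direction[0]))) % 180.0
    return 0.0 if abs(ang - 180.0) < 1e-12 else ang
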