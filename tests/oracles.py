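"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the package's own algorithms: flood fill instead of
Union-Find, O(n^3) hull checks instead of monotone chain, dense rotation
scans instead of rotating calipers.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_partition(mask: np.ndarray) -> list[frozenset]:
    """8-connected components of the foreground via BFS flood fill."""
    mask = np.asarray(mask)
    h, w = mask.shape
    seen = np.zeros((h, w), dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            comp = set()
            queue = deque([(r, c)])
            seen[r, c] = True
            while queue:
                cr, cc = queue.popleft()
                comp.add((cr, cc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc2 = cr + dr, cc + dc
                        if (0 <= rr < h and 0 <= cc2 < w and mask[rr, cc2]
                                and not seen[rr, cc2]):
                            seen[rr, cc2] = True
                            queue.append((rr, cc2))
            comps.append(frozenset(comp))
    return comps


def brute_hull(points: np.ndarray) -> set[tuple[float, float]]:
    """Hull vertex set by the O(n^3) supporting-line test.

    A pair (i, j) spans a supporting line when every point lies on one side
    of it; the hull vertices are the extreme points of the collinear runs on
    supporting lines.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    n = len(pts)
    if n <= 2:
        return {tuple(p) for p in pts}
    eps = 1e-9
    verts: set[tuple[float, float]] = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            rel = pts - pts[i]
            side = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            if (side <= eps).all() or (side >= -eps).all():
                on_line = pts[np.abs(side) <= eps]
                proj = on_line @ d
                verts.add(tuple(on_line[proj.argmin()]))
                verts.add(tuple(on_line[proj.argmax()]))
    return verts


def brute_max_pairwise(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def rotation_scan_min_width(points: np.ndarray, step_deg: float = 0.001) -> float:
    pts = np.asarray(points, dtype=float)
    ang = np.radians(np.arange(0.0, 180.0, step_deg))
    dirs = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    proj = pts @ dirs.T
    return float((proj.max(axis=0) - proj.min(axis=0)).min())


def rotation_scan_min_rect_area(points: np.ndarray, step_deg: float = 0.01) -> float:
    pts = np.asarray(points, dtype=float)
    ang = np.radians(np.arange(0.0, 90.0, step_deg))
    u = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    v = np.stack([-np.sin(ang), np.cos(ang)], axis=1)
    pu = pts @ u.T
    pv = pts @ v.T
    areas = (pu.max(axis=0) - pu.min(axis=0)) * (pv.max(axis=0) - pv.min(axis=0))
    return float(areas.min())


def boundary_pixels(mask: np.ndarray) -> list[tuple[int, int]]:
    """Region pixels with at least one 8-neighbor outside the region."""
    mask = np.asarray(mask)
    h, w = mask.shape
    out = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            edge = False
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                        edge = True
            if edge:
                out.append((r, c))
    return out
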