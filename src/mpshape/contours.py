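"""Contour tracing and perimeter measurement for a labeled region.

The outer boundary and the boundary around every hole are traced with
Moore-neighbor tracing using Jacob's stopping criterion (the walk ends when
a (pixel, backtrack) state repeats, i.e. the start pixel is re-entered from
the same direction).  Contour points are region pixels; a hole is a
4-connected background component that does not touch the mask border
(standard duality with the 8-connected foreground).

Perimeter uses chain-code step weights: 1 for axial steps, sqrt(2) for
diagonal steps.  No corner-corrected (sub-pixel) estimator is applied.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .labeling import Region

SQRT2 = math.sqrt(2.0)

# Moore neighborhood in clockwise order (row grows downward):
# E, SE, S, SW, W, NW, N, NE
_NBRS = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))
_NBR_INDEX = {d: i for i, d in enumerate(_NBRS)}

OUTER = "outer"
INNER = "inner"


@dataclass(frozen=True)
class Contour:
    """A closed pixel path; consecutive points (cyclically) are 8-neighbors."""

    points: tuple[tuple[int, int], ...]
    kind: str  # "outer" | "inner"
    parent: "Contour | None" = None

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ContourSet:
    """One outer contour plus zero or more inner (hole) contours."""

    outer: Contour
    inners: tuple[Contour, ...] = ()

    def all_points(self) -> np.ndarray:
        """All contour points, outer and inner, as an (n, 2) array."""
        pts = list(self.outer.points)
        for inner in self.inners:
            pts.extend(inner.points)
        return np.array(pts, dtype=np.int64)


def _moore_trace(mask: np.ndarray, start: tuple[int, int], backtrack: tuple[int, int]):
    """Walk the boundary clockwise from ``start`` given an initial backtrack.

    Returns the closed cycle of visited pixels (the walk truncated at the
    first repeated (pixel, backtrack) state).  A pixel with no foreground
    neighbor yields the single-point walk.
    """
    h, w = mask.shape
    walk = [start]
    seen = {(start, backtrack): 0}
    cur, back = start, backtrack
    max_steps = 8 * int(mask.sum()) + 64
    for _ in range(max_steps):
        bi = _NBR_INDEX[(back[0] - cur[0], back[1] - cur[1])]
        nxt = None
        for k in range(1, 9):
            dr, dc = _NBRS[(bi + k) % 8]
            r, c = cur[0] + dr, cur[1] + dc
            if 0 <= r < h and 0 <= c < w and mask[r, c]:
                pr, pc = _NBRS[(bi + k - 1) % 8]
                back = (cur[0] + pr, cur[1] + pc)
                nxt = (r, c)
                break
        if nxt is None:
            return walk  # isolated pixel
        cur = nxt
        state = (cur, back)
        if state in seen:
            return walk[seen[state]:]
        seen[state] = len(walk)
        walk.append(cur)
    raise RuntimeError("contour trace failed to close")  # pragma: no cover


def _rotate_min_first(points: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    i = min(range(len(points)), key=points.__getitem__)
    return tuple(points[i:] + points[:i])


def _find_holes(mask: np.ndarray) -> list[np.ndarray]:
    """4-connected background components not touching the border.

    Returns one (n, 2) pixel array per hole.
    """
    h, w = mask.shape
    bg = mask == 0
    outside = np.zeros((h, w), dtype=bool)
    queue: deque[tuple[int, int]] = deque()
    for r in range(h):
        for c in (0, w - 1):
            if bg[r, c] and not outside[r, c]:
                outside[r, c] = True
                queue.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if bg[r, c] and not outside[r, c]:
                outside[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and bg[rr, cc] and not outside[rr, cc]:
                outside[rr, cc] = True
                queue.append((rr, cc))

    hole_mask = bg & ~outside
    holes = []
    visited = np.zeros((h, w), dtype=bool)
    for r, c in zip(*np.nonzero(hole_mask)):
        if visited[r, c]:
            continue
        comp = [(int(r), int(c))]
        visited[r, c] = True
        queue.append((int(r), int(c)))
        while queue:
            cr, cc = queue.popleft()
            for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
                rr, cc2 = cr + dr, cc + dc
                if 0 <= rr < h and 0 <= cc2 < w and hole_mask[rr, cc2] and not visited[rr, cc2]:
                    visited[rr, cc2] = True
                    comp.append((rr, cc2))
                    queue.append((rr, cc2))
        holes.append(np.array(sorted(comp), dtype=np.int64))
    return holes


def trace_contours(region: Region, mask: np.ndarray | None = None) -> ContourSet:
    """Trace the outer contour and one inner contour per hole of a region.

    ``mask`` may be the full binary image; only the pixels of ``region`` are
    traced.  When omitted it is rebuilt from the region's pixel set.
    """
    if region.area < 1:
        raise ValueError("empty region")
    if mask is None:
        h = int(region.pixels[:, 0].max()) + 2
        w = int(region.pixels[:, 1].max()) + 2
        rmask = region.to_mask((h, w))
    else:
        rmask = region.to_mask(np.asarray(mask).shape)

    # outer: start at the lexicographically smallest region pixel; the pixel
    # above it is guaranteed background
    order = np.lexsort((region.pixels[:, 1], region.pixels[:, 0]))
    sr, sc = (int(v) for v in region.pixels[order[0]])
    walk = _moore_trace(rmask, (sr, sc), (sr - 1, sc))
    outer = Contour(points=_rotate_min_first(walk), kind=OUTER)

    inners = []
    for hole in _find_holes(rmask):
        hr, hc = (int(v) for v in hole[0])  # topmost-leftmost hole pixel
        # the pixel above it cannot be background: it would belong to the
        # same 4-connected hole, contradicting topmost-ness
        walk = _moore_trace(rmask, (hr - 1, hc), (hr, hc))
        inners.append(Contour(points=_rotate_min_first(walk), kind=INNER, parent=outer))
    return ContourSet(outer=outer, inners=tuple(inners))


def contour_length(contour: Contour) -> float:
    """Cyclic path length: axial steps count 1, diagonal steps sqrt(2)."""
    pts = contour.points
    n = len(pts)
    if n <= 1:
        return 0.0
    total = 0.0
    for i in range(n):
        r0, c0 = pts[i]
        r1, c1 = pts[(i + 1) % n]
        dr, dc = abs(r1 - r0), abs(c1 - c0)
        if dr > 1 or dc > 1 or (dr == 0 and dc == 0):
            raise ValueError("broken contour")
        total += SQRT2 if dr + dc == 2 else 1.0
    return total


def region_perimeter(cs: ContourSet) -> tuple[float, float]:
    """(outer length, total length including all inner contours)."""
    outer_len = contour_length(cs.outer)
    total_len = outer_len + sum(contour_length(inner) for inner in cs.inners)
    return outer_len, total_len


def contours_to_rows(cs: ContourSet):
    """Flatten a contour set into (contour_id, kind, point_index, row, col) rows."""
    rows = []
    for cid, contour in enumerate([cs.outer, *cs.inners]):
        for i, (r, c) in enumerate(contour.points):
            rows.append((cid, contour.kind, i, r, c))
    return rows
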