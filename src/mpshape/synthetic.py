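"""Synthetic fixtures with analytic ground truth.

Rasterization uses the pixel-center inclusion rule: pixel (r, c) is
foreground iff its center lies inside the continuous shape.  Rectangles use
a half-open interval along each side so an axis-aligned L×W rectangle on an
aligned grid covers exactly L·W pixel centers.  Fibers are the set of
pixels within width/2 of a centerline polyline; a twisted fiber wraps its
centerline into a closed loop so the mask encloses a hole.

``render_scene`` turns a mask into a grayscale scene (noisy background plus
item at a distinct level) so the full pipeline can be exercised without any
external image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DISK = "disk"
RECTANGLE = "rectangle"
ELLIPSE = "ellipse"
FIBER = "fiber"
TWISTED_FIBER = "twisted_fiber"


@dataclass(frozen=True)
class ShapeSpec:
    """Parametric description of one synthetic item.

    Which size fields are required depends on ``kind``:
    disk -> radius; rectangle -> sides (L, W); ellipse -> semi_axes (a, b);
    fiber/twisted_fiber -> centerline (list of (row, col)) and width.
    ``angle_deg`` rotates rectangles/ellipses counterclockwise from the
    column axis; ``center`` is the shape center in (row, col).
    """

    kind: str
    center: tuple[float, float] | None = None
    radius: float | None = None
    sides: tuple[float, float] | None = None
    semi_axes: tuple[float, float] | None = None
    angle_deg: float = 0.0
    centerline: tuple[tuple[float, float], ...] | None = None
    width: float | None = None


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth for a rasterized shape (all sizes in pixels)."""

    kind: str
    true_area: float
    true_length: float
    true_width: float
    true_axes: tuple[float, float] | None
    has_hole: bool
    true_fiber_length: float | None


def _grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.mgrid[0:h, 0:w]
    return rr.astype(float), cc.astype(float)


def _rotated_frame(rr, cc, center, angle_deg):
    r0, c0 = center
    th = math.radians(angle_deg)
    dc, dr = cc - c0, rr - r0
    u = dc * math.cos(th) + dr * math.sin(th)
    v = -dc * math.sin(th) + dr * math.cos(th)
    return u, v


def _polyline_distance(rr, cc, pts: np.ndarray) -> np.ndarray:
    """Euclidean distance of every pixel center to a polyline."""
    d = np.full(rr.shape, np.inf)
    p = np.stack([rr, cc], axis=-1)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            t = np.zeros(rr.shape)
        else:
            t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
        proj = a + t[..., None] * ab
        d = np.minimum(d, np.hypot(p[..., 0] - proj[..., 0], p[..., 1] - proj[..., 1]))
    return d


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.hypot(*(np.diff(pts, axis=0).T)).sum())


def rasterize(spec: ShapeSpec, canvas_h: int, canvas_w: int) -> tuple[np.ndarray, GroundTruth]:
    """Rasterize a shape onto a canvas; error if it touches or leaves it."""
    rr, cc = _grid(canvas_h, canvas_w)
    center = spec.center if spec.center is not None else ((canvas_h - 1) / 2.0, (canvas_w - 1) / 2.0)

    if spec.kind == DISK:
        if spec.radius is None or spec.radius <= 0:
            raise ValueError("disk requires a positive radius")
        r0, c0 = center
        mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= spec.radius ** 2
        truth = GroundTruth(DISK, math.pi * spec.radius ** 2, 2 * spec.radius,
                            2 * spec.radius, (spec.radius, spec.radius), False, None)
    elif spec.kind == RECTANGLE:
        if spec.sides is None or min(spec.sides) <= 0:
            raise ValueError("rectangle requires positive sides")
        L, W = max(spec.sides), min(spec.sides)
        u, v = _rotated_frame(rr, cc, center, spec.angle_deg)
        mask = (u >= -L / 2) & (u < L / 2) & (v >= -W / 2) & (v < W / 2)
        truth = GroundTruth(RECTANGLE, L * W, L, W, None, False, None)
    elif spec.kind == ELLIPSE:
        if spec.semi_axes is None or min(spec.semi_axes) <= 0:
            raise ValueError("ellipse requires positive semi-axes")
        a, b = max(spec.semi_axes), min(spec.semi_axes)
        u, v = _rotated_frame(rr, cc, center, spec.angle_deg)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        truth = GroundTruth(ELLIPSE, math.pi * a * b, 2 * a, 2 * b, (a, b), False, None)
    elif spec.kind in (FIBER, TWISTED_FIBER):
        if spec.centerline is None or len(spec.centerline) < 2:
            raise ValueError("fiber requires a centerline of at least 2 points")
        if spec.width is None or spec.width <= 0:
            raise ValueError("fiber requires a positive width")
        pts = np.asarray(spec.centerline, dtype=float)
        mask = _polyline_distance(rr, cc, pts) <= spec.width / 2.0
        arclen = _polyline_length(pts)
        truth = GroundTruth(spec.kind,
                            arclen * spec.width + math.pi * (spec.width / 2.0) ** 2,
                            arclen + spec.width, spec.width, None,
                            spec.kind == TWISTED_FIBER, arclen)
    else:
        raise ValueError(f"unknown shape kind {spec.kind!r}")

    if not mask.any():
        raise ValueError("shape out of canvas")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError("shape out of canvas")
    return mask.astype(np.uint8), truth


def render_scene(mask: np.ndarray, bg_level: int, item_level: int,
                 noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Grayscale scene: item pixels near ``item_level``, background near
    ``bg_level``, Gaussian noise clipped to [0, 255]."""
    for name, level in (("bg_level", bg_level), ("item_level", item_level)):
        if not 0 <= level <= 255:
            raise ValueError(f"{name} must be in [0, 255]")
    if bg_level == item_level:
        raise ValueError("zero contrast between item and background")
    mask = np.asarray(mask)
    scene = np.where(mask > 0, float(item_level), float(bg_level))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        scene = scene + rng.normal(0.0, noise_sd, size=scene.shape)
    return np.clip(np.floor(scene + 0.5), 0, 255).astype(np.uint8)


# --- randomized population -------------------------------------------------

CANVAS = 192
_MARGIN = 24
BG_LEVEL = 200
ITEM_LEVEL = 60
NOISE_SD = 4.0


def _random_particle(rng: np.random.Generator) -> ShapeSpec:
    jitter = tuple((CANVAS - 1) / 2.0 + rng.uniform(-8, 8, size=2))
    kind = rng.choice([DISK, RECTANGLE, ELLIPSE])
    if kind == DISK:
        return ShapeSpec(DISK, center=jitter, radius=float(rng.uniform(12, 30)))
    if kind == RECTANGLE:
        L = float(rng.uniform(30, 70))
        W = float(rng.uniform(0.45, 0.95) * L)
        return ShapeSpec(RECTANGLE, center=jitter, sides=(L, W),
                         angle_deg=float(rng.uniform(0, 180)))
    a = float(rng.uniform(16, 38))
    b = float(rng.uniform(0.45, 0.95) * a)
    return ShapeSpec(ELLIPSE, center=jitter, semi_axes=(a, b),
                     angle_deg=float(rng.uniform(0, 180)))


def _random_fiber(rng: np.random.Generator) -> ShapeSpec:
    # quadratic Bezier whose control points stay inside the margin
    lo, hi = _MARGIN, CANVAS - 1 - _MARGIN
    p0 = rng.uniform(lo, hi, size=2)
    p2 = rng.uniform(lo, hi, size=2)
    while np.hypot(*(p2 - p0)) < 90:  # keep fibers long
        p2 = rng.uniform(lo, hi, size=2)
    p1 = rng.uniform(lo, hi, size=2)
    t = np.linspace(0.0, 1.0, 160)[:, None]
    curve = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2
    return ShapeSpec(FIBER, centerline=tuple(map(tuple, curve)),
                     width=float(rng.uniform(2.5, 4.5)))


def make_population(n_particles: int, n_fibers: int, seed: int,
                    noise_sd: float = NOISE_SD) -> list[tuple[np.ndarray, GroundTruth]]:
    """Reproducible mixed population of grayscale scenes with ground truth.

    Items are dark (level 60) on a light background (level 200); the default
    threshold of 127 with dark polarity recovers each mask.
    """
    if n_particles < 0 or n_fibers < 0:
        raise ValueError("population counts must be >= 0")
    rng = np.random.default_rng(seed)
    scenes = []
    for i in range(n_particles + n_fibers):
        spec = _random_particle(rng) if i < n_particles else _random_fiber(rng)
        mask, truth = rasterize(spec, CANVAS, CANVAS)
        scene_seed = int(rng.integers(0, 2 ** 31 - 1))
        gray = render_scene(mask, BG_LEVEL, ITEM_LEVEL, noise_sd, scene_seed)
        scenes.append((gray, truth))
    return scenes
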