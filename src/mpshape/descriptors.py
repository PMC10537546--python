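"""Shape descriptors of a labeled region.

Conventions:

* circularity = F / (d_max^2 * pi), clamped to [0, 1]; 1 for an ideal disk,
  smaller for elongated or perforated shapes.
* compactness = P^2 / (4 * F * pi) with P the TOTAL perimeter (outer plus
  inner contours); 1 for an ideal disk, larger for elongated or perforated
  shapes.
* Ra/Rb are the semi-axes of the moment-equivalent ellipse (a continuous
  disk of radius r yields Ra = Rb = r).
* fiber length is half the OUTER contour length.

Degenerate single-pixel regions are reported as circularity 1, compactness
0 and zero axes, flagged rather than dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contours import ContourSet, region_perimeter
from .geometry import Hull, RectangleFit
from .labeling import Region

FLAG_SINGLE_PIXEL = "single_pixel"
FLAG_DEGENERATE_WIDTH = "degenerate_width"
FLAG_CLAMPED_CIRCULARITY = "clamped_circularity"


@dataclass(frozen=True)
class MomentSet:
    """Normalized central geometric moments M11, M20, M02.

    M_ij = (1/F) * sum over region pixels of (r0 - r)^i * (c0 - c)^j.
    """

    M11: float
    M20: float
    M02: float


@dataclass(frozen=True)
class DescriptorRecord:
    F: float
    outer_len: float
    total_len: float
    d_max: float
    circularity: float
    compactness: float
    ferret_min: float
    ferret_max: float
    rect_length: float
    rect_width: float
    rect_angle: float
    elongatedness: float
    Ra: float
    Rb: float
    fiber_length: float
    flags: frozenset[str] = frozenset()

    #: record fields that scale linearly with pixel size (F scales with its square)
    LINEAR_FIELDS = (
        "outer_len", "total_len", "d_max", "ferret_min", "ferret_max",
        "rect_length", "rect_width", "Ra", "Rb", "fiber_length",
    )

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in (
            "F", "outer_len", "total_len", "d_max", "circularity", "compactness",
            "ferret_min", "ferret_max", "rect_length", "rect_width", "rect_angle",
            "elongatedness", "Ra", "Rb", "fiber_length")}
        d["flags"] = ";".join(sorted(self.flags))
        return d


def area(region: Region) -> int:
    """Region area F: the number of pixels."""
    if region.area < 1:
        raise ValueError("empty region")
    return region.area


def moments(region: Region) -> MomentSet:
    """Normalized central moments of the region's pixel coordinates."""
    pix = region.pixels.astype(float)
    r0, c0 = pix.mean(axis=0)
    dr = r0 - pix[:, 0]
    dc = c0 - pix[:, 1]
    f = pix.shape[0]
    return MomentSet(
        M11=float((dr * dc).sum() / f),
        M20=float((dr * dr).sum() / f),
        M02=float((dc * dc).sum() / f),
    )


def ellipse_axes(m: MomentSet) -> tuple[float, float]:
    """Semi-axes (Ra, Rb) of the moment-equivalent ellipse, Ra >= Rb."""
    disc = math.sqrt((m.M20 - m.M02) ** 2 + 4.0 * m.M11 ** 2)
    ra_sq = 8.0 * (m.M20 + m.M02 + disc)
    rb_sq = 8.0 * (m.M20 + m.M02 - disc)
    if rb_sq < 0:
        if rb_sq < -1e-9:
            raise ArithmeticError("negative radicand in ellipse axes")
        rb_sq = 0.0
    return math.sqrt(ra_sq) / 2.0, math.sqrt(rb_sq) / 2.0


def d_max(region: Region, cs: ContourSet) -> float:
    """Max Euclidean distance from the centroid to any contour point."""
    r0, c0 = region.centroid
    pts = cs.all_points().astype(float)
    d = np.hypot(pts[:, 0] - r0, pts[:, 1] - c0)
    return float(d.max())


def circularity(F: int, dmax: float, clamp: bool = True) -> float:
    """F / (d_max^2 * pi); single-pixel regions (d_max = 0) give 1."""
    if F < 1:
        raise ValueError("empty region")
    if dmax == 0.0:
        return 1.0
    value = F / (dmax * dmax * math.pi)
    return min(max(value, 0.0), 1.0) if clamp else value


def compactness(P: float, F: int) -> float:
    """P^2 / (4 * F * pi) with P the total (outer + inner) perimeter."""
    if F < 1:
        raise ValueError("empty region")
    if P < 0:
        raise ValueError("negative perimeter")
    return (P * P) / (4.0 * F * math.pi)


def elongatedness(rect: RectangleFit) -> float:
    """Ratio length/width of the minimum-area rectangle; NaN when width = 0."""
    if rect.width == 0.0:
        return math.nan
    return rect.length / rect.width


def fiber_length(outer_len: float) -> float:
    """Half the outer contour length (out-and-back tracing of a fiber)."""
    if outer_len < 0:
        raise ValueError("negative perimeter")
    return outer_len / 2.0


def describe(region: Region, cs: ContourSet, hull: Hull, rect: RectangleFit,
             m: MomentSet) -> DescriptorRecord:
    """Assemble the full descriptor record from the per-stage results."""
    from .geometry import ferret_diameters

    F = area(region)
    outer_len, total_len = region_perimeter(cs)
    dmax = d_max(region, cs)
    flags = set()
    if F == 1:
        flags.add(FLAG_SINGLE_PIXEL)
        circ, comp = 1.0, 0.0
    else:
        raw = circularity(F, dmax, clamp=False)
        circ = circularity(F, dmax)
        if raw > 1.0:
            flags.add(FLAG_CLAMPED_CIRCULARITY)
        comp = compactness(total_len, F)
    fmin, fmax = ferret_diameters(hull)
    elong = elongatedness(rect)
    if rect.width == 0.0:
        flags.add(FLAG_DEGENERATE_WIDTH)
    ra, rb = ellipse_axes(m)
    return DescriptorRecord(
        F=F,
        outer_len=outer_len,
        total_len=total_len,
        d_max=dmax,
        circularity=circ,
        compactness=comp,
        ferret_min=fmin,
        ferret_max=fmax,
        rect_length=rect.length,
        rect_width=rect.width,
        rect_angle=rect.angle,
        elongatedness=elong,
        Ra=ra,
        Rb=rb,
        fiber_length=fiber_length(outer_len),
        flags=frozenset(flags),
    )
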