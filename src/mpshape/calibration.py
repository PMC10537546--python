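"""Pixel-to-SI conversion of descriptor records.

The physical pixel size is supplied either directly (mm per pixel) or as a
field-of-view width divided by the image width in pixels; square pixels are
assumed.  Dimensionless descriptors (circularity, compactness,
elongatedness) and the rectangle angle are unchanged by calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .descriptors import DescriptorRecord


@dataclass(frozen=True)
class CalibrationSpec:
    mm_per_pixel: float | None = None
    fov_width_mm: float | None = None
    image_width_px: int | None = None
    magnification: str | None = None  # free-text metadata only


def resolve_scale(spec: CalibrationSpec) -> float:
    """Return mm per pixel from exactly one of the two supported forms."""
    direct = spec.mm_per_pixel is not None
    fov = spec.fov_width_mm is not None or spec.image_width_px is not None
    if direct and fov:
        raise ValueError("give either mm_per_pixel or fov_width_mm + image_width_px, not both")
    if direct:
        scale = float(spec.mm_per_pixel)
    elif spec.fov_width_mm is not None and spec.image_width_px is not None:
        if spec.image_width_px <= 0:
            raise ValueError("image_width_px must be positive")
        scale = float(spec.fov_width_mm) / float(spec.image_width_px)
    else:
        raise ValueError("no calibration provided")
    if scale <= 0:
        raise ValueError("mm_per_pixel must be positive")
    return scale


def to_si(rec: DescriptorRecord, mm_per_pixel: float) -> DescriptorRecord:
    """Scale linear descriptors by ``mm_per_pixel`` and the area by its square."""
    if mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be positive")
    updates = {name: getattr(rec, name) * mm_per_pixel for name in DescriptorRecord.LINEAR_FIELDS}
    updates["F"] = rec.F * mm_per_pixel * mm_per_pixel
    return replace(rec, **updates)
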