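"""Image pretreatment: grayscale conversion, cropping and fixed-value thresholding.

All images are numpy arrays with ``(row, col)`` indexing, origin at the
top-left corner and pixel centers at integer coordinates.  Grayscale images
are ``uint8`` H×W arrays; RGB images are ``uint8`` H×W×3; binary masks are
``uint8`` H×W arrays holding only 0 (background) and 1 (item).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: ITU-R BT.601 luma weights used for the RGB -> grayscale transform.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

DARK = "dark"
LIGHT = "light"


@dataclass(frozen=True)
class ThresholdSpec:
    """Fixed intensity threshold with item polarity.

    ``polarity="dark"`` selects pixels with intensity <= ``th`` (item darker
    than the background); ``polarity="light"`` selects intensity >= ``th``.
    Both comparisons are inclusive.
    """

    th: int = 127
    polarity: str = DARK

    def __post_init__(self) -> None:
        if not 0 <= self.th <= 255:
            raise ValueError(f"threshold must be in [0, 255], got {self.th}")
        if self.polarity not in (DARK, LIGHT):
            raise ValueError(f"polarity must be 'dark' or 'light', got {self.polarity!r}")


@dataclass(frozen=True)
class ContrastReport:
    """Foreground fraction of a thresholded image plus a sanity flag."""

    foreground_fraction: float
    flagged: bool
    max_fraction: float


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to 8-bit grayscale (BT.601, round half-up).

    Already-gray H×W inputs pass through unchanged.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty input")
    if img.ndim == 2:
        return img.astype(np.uint8, copy=False)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H×W or H×W×3 image, got shape {img.shape}")
    wr, wg, wb = LUMA_WEIGHTS
    luma = wr * img[..., 0] + wg * img[..., 1] + wb * img[..., 2]
    # round half-up; np.rint rounds half-to-even which disagrees at .5
    return np.floor(luma + 0.5).astype(np.uint8)


def crop(img: np.ndarray, top: int, left: int, height: int, width: int) -> np.ndarray:
    """Extract a window; the window must lie fully inside the image.

    The caller is responsible for remembering ``(top, left)`` when contour
    coordinates must be reported in the original-image frame (the pipeline
    records them per image).
    """
    img = np.asarray(img)
    h, w = img.shape[:2]
    if height < 1 or width < 1:
        raise ValueError("crop out of bounds")
    if top < 0 or left < 0 or top + height > h or left + width > w:
        raise ValueError("crop out of bounds")
    return img[top : top + height, left : left + width]


def threshold(img: np.ndarray, spec: ThresholdSpec) -> np.ndarray:
    """Binarize a grayscale image: 1 = item pixel, 0 = background."""
    img = np.asarray(img)
    if spec.polarity == DARK:
        mask = img <= spec.th
    else:
        mask = img >= spec.th
    return mask.astype(np.uint8)


def contrast_report(
    img: np.ndarray, spec: ThresholdSpec, max_fraction: float = 0.5
) -> ContrastReport:
    """Flag images whose thresholded foreground is empty or implausibly large.

    A fraction of 0 means nothing separated from the background (e.g. a
    transparent item); a fraction above ``max_fraction`` usually means wrong
    polarity or an unthresholdable image.
    """
    mask = threshold(img, spec)
    frac = float(mask.mean()) if mask.size else 0.0
    flagged = frac == 0.0 or frac > max_fraction
    return ContrastReport(foreground_fraction=frac, flagged=flagged, max_fraction=max_fraction)
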