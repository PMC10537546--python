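"""Reading and writing of PNG/TIFF/JPEG images as numpy arrays."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

#: file suffixes accepted by the pipeline input scan
IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


def read_image(path) -> np.ndarray:
    """Load an image as uint8 H×W (gray) or H×W×3 (RGB); alpha is dropped."""
    with Image.open(path) as im:
        if im.mode in ("RGBA", "P", "LA"):
            im = im.convert("RGB")
        elif im.mode not in ("RGB", "L"):
            im = im.convert("L")
        arr = np.asarray(im)
    return arr.astype(np.uint8, copy=False)


def write_image(arr: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(arr)).save(path)


def find_images(paths) -> list[Path]:
    """Expand files/directories into a sorted list of image paths."""
    found: list[Path] = []
    for p in map(Path, paths):
        if p.is_dir():
            found.extend(q for q in sorted(p.iterdir())
                         if q.suffix.lower() in IMAGE_SUFFIXES)
        elif p.exists():
            found.append(p)
        else:
            raise FileNotFoundError(str(p))
    return found
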