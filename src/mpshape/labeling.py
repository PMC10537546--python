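"""Two-pass connected-component labeling with a Union-Find forest.

Foreground connectivity is 8-connected.  The image is scanned row-major from
the top-left; pass 1 assigns provisional labels from the already-visited
neighbors (up-left, up, up-right, left), recording label unions whenever two
distinct provisional labels meet.  Pass 2 resolves every provisional label
to its root and compacts the roots into the contiguous range 1..K.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np


class UnionFindForest:
    """Disjoint-set forest over positive integer labels.

    ``union`` attaches the larger root beneath the smaller one, so the root
    of every equivalence class is its minimum label; ``find`` applies path
    compression.
    """

    def __init__(self) -> None:
        self._parent: list[int] = [0]  # index 0 unused; labels start at 1

    def make_label(self) -> int:
        label = len(self._parent)
        self._parent.append(label)
        return label

    def find(self, x: int) -> int:
        parent = self._parent
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return ra
        if rb < ra:
            ra, rb = rb, ra
        self._parent[rb] = ra
        return ra

    def __len__(self) -> int:
        return len(self._parent) - 1


@dataclass(frozen=True)
class Region:
    """A labeled 8-connected set of foreground pixels."""

    label: int
    pixels: np.ndarray  # (n, 2) int array of (row, col)

    @property
    def area(self) -> int:
        """Pixel count F of the region."""
        return int(self.pixels.shape[0])

    @property
    def centroid(self) -> tuple[float, float]:
        """Center of gravity (r0, c0) as the mean pixel coordinate."""
        r0, c0 = self.pixels.mean(axis=0)
        return float(r0), float(c0)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Render the region as a {0,1} mask of the given image shape."""
        mask = np.zeros(shape, dtype=np.uint8)
        mask[self.pixels[:, 0], self.pixels[:, 1]] = 1
        return mask


def label_components(mask: np.ndarray) -> tuple[np.ndarray, list[Region]]:
    """Label 8-connected foreground components of a binary mask.

    Returns the label image (0 = background, components numbered 1..K in
    scan order of their first pixel) and the list of regions with pixel
    sets.  An empty mask yields an all-zero label image and no regions.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected 2-D mask, got shape {mask.shape}")
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int32)
    uf = UnionFindForest()
    find = uf.find
    union = uf.union

    for r in range(h):
        cur = labels[r]
        prev = labels[r - 1] if r > 0 else None
        for c in np.flatnonzero(mask[r]):
            c = int(c)
            best = 0
            left = int(cur[c - 1]) if c > 0 else 0
            if left:
                best = find(left)
            if prev is not None:
                lo = c - 1 if c > 0 else 0
                hi = c + 2 if c + 1 < w else w
                for lab in prev[lo:hi]:
                    lab = int(lab)
                    if lab:
                        root = find(lab)
                        if best == 0 or root < best:
                            if best:
                                union(best, root)
                            best = root
                        elif root != best:
                            union(best, root)
            cur[c] = best if best else uf.make_label()

    # pass 2: resolve provisional labels to roots, compact to 1..K
    n = len(uf)
    lut = np.zeros(n + 1, dtype=np.int32)
    k = 0
    for lab in range(1, n + 1):
        root = find(lab)
        if root == lab:
            k += 1
            lut[lab] = k
    for lab in range(1, n + 1):
        lut[lab] = lut[find(lab)]
    labels = lut[labels]

    regions = _extract_regions(labels, k)
    return labels, regions


def _extract_regions(labels: np.ndarray, k: int) -> list[Region]:
    rows, cols = np.nonzero(labels)
    if rows.size == 0:
        return []
    labs = labels[rows, cols]
    order = np.argsort(labs, kind="stable")
    pixels = np.column_stack([rows, cols])[order]
    labs = labs[order]
    bounds = np.searchsorted(labs, np.arange(1, k + 2))
    return [
        Region(label=i + 1, pixels=pixels[bounds[i] : bounds[i + 1]])
        for i in range(k)
    ]


def sort_and_select_largest(regions: list[Region]) -> Region:
    """Return the region of maximal area; ties go to the smallest label."""
    if not regions:
        raise ValueError("no region found")
    return max(regions, key=lambda reg: (reg.area, -reg.label))


def save_label_image(labels: np.ndarray, path) -> None:
    """Debug export of the label image as a 16-bit grayscale PNG."""
    from PIL import Image

    if labels.max(initial=0) > 0xFFFF:
        raise ValueError("more than 65535 labels cannot be saved as 16-bit PNG")
    Image.fromarray(labels.astype(np.uint16), mode="I;16").save(path)


def save_region_table(regions: list[Region], path) -> None:
    """Debug export: one CSV row per region (label, area, centroid)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "area", "centroid_row", "centroid_col"])
        for reg in regions:
            r0, c0 = reg.centroid
            writer.writerow([reg.label, reg.area, f"{r0:.6g}", f"{c0:.6g}"])
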