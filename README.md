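# mpshape

Pixel-level morphometry of single items (e.g. microplastic fibers and
particles) in stereomicroscope images.

Each input image is expected to contain one item that is darker or lighter
than a roughly uniform background. The pipeline is:

1. **pretreat** — RGB → grayscale (BT.601, round half-up), optional crop,
   fixed-value thresholding with dark/light polarity, and a contrast check
   that flags unthresholdable images.
2. **labeling** — two-pass connected-component labeling with a Union–Find
   forest, 8-connected foreground; the largest region is selected.
3. **contours** — Moore-neighbor tracing (Jacob's stopping criterion) of the
   outer boundary and of the boundary around every hole; perimeter uses
   chain-code weights (1 axial, √2 diagonal).
4. **geometry** — monotone-chain convex hull, rotating-calipers min/max
   ferret diameters, minimum-area oriented bounding rectangle.
5. **descriptors** — area F, outer/total perimeter, max centroid-to-contour
   distance, circularity `F/(d_max²·π)`, compactness `P²/(4Fπ)` (total
   perimeter), elongatedness (rectangle length/width), moment-ellipse
   semi-axes Ra/Rb, fiber length (half the outer perimeter).
6. **calibration** — optional pixel → mm conversion from a pixel size or a
   field-of-view width.

A **synthetic** module rasterizes disks, rotated rectangles and ellipses,
straight/curved fibers and self-looping (twisted) fibers with analytic
ground truth, and renders them as noisy grayscale scenes, so the whole
pipeline is testable without any external image.

## CLI

```sh
# generate a directory of synthetic scenes plus ground_truth.csv
mpshape fixtures --n-particles 5 --n-fibers 5 --seed 1 -o fixtures/

# measure every image in a directory (or individual files)
mpshape run fixtures/ --threshold 127 --polarity dark \
    --mm-per-pixel 0.005 -o out/

# per-descriptor mean/min/max/SD table (sample SD, n-1)
mpshape summarize out/descriptors.csv -o out/summary.csv
```

`mpshape run` writes `descriptors.csv` (one row per analyzed image, pixel
units plus `_mm`/`_mm2` columns when calibrated) and `skipped.csv` for
images that failed the contrast check. Useful flags: `--crop T,L,H,W`,
`--max-foreground 0.5`, `--pixel-extent` (measure geometry over whole pixel
squares instead of pixel centers, adding ~1 px to ferrets),
`--fov-width-mm` + `--image-width-px` as an alternative calibration.

## Conventions

* Coordinates are `(row, col)`, 0-based, origin top-left, pixel centers at
  integer positions; geometry operates on pixel centers unless
  `--pixel-extent` is given.
* Threshold comparison is inclusive (`<= th` for dark items, `>= th` for
  light items).
* Circularity is clamped to [0, 1] (rasterization can push the raw value
  marginally above 1); compactness uses the total perimeter including hole
  boundaries; fiber length uses the outer contour only.
* Single-pixel regions report circularity 1, compactness 0 and zero axes,
  flagged `single_pixel` rather than dropped.
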