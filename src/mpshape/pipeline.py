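"""End-to-end orchestration: image -> descriptor table.

Per image: grayscale -> optional crop -> threshold -> contrast check ->
label (Union-Find) -> select the largest region -> trace contours -> hull /
rectangle / moments -> descriptor record -> optional SI calibration.
Images that fail the contrast check (empty or implausible foreground) are
recorded in a skip report rather than aborting the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imgio
from .calibration import CalibrationSpec, resolve_scale, to_si
from .contours import trace_contours
from .descriptors import DescriptorRecord, describe, moments
from .geometry import convex_hull, min_area_rectangle, with_pixel_extent
from .labeling import label_components, sort_and_select_largest
from .pretreat import ThresholdSpec, contrast_report, crop, threshold, to_grayscale

log = logging.getLogger("mpshape")

#: descriptor columns emitted per image, in order
PIXEL_COLUMNS = [
    "F", "outer_len", "total_len", "d_max", "circularity", "compactness",
    "ferret_min", "ferret_max", "rect_length", "rect_width", "rect_angle",
    "elongatedness", "Ra", "Rb", "fiber_length",
]
SI_COLUMNS = [
    "F_mm2", "outer_len_mm", "total_len_mm", "d_max_mm", "ferret_min_mm",
    "ferret_max_mm", "rect_length_mm", "rect_width_mm", "Ra_mm", "Rb_mm",
    "fiber_length_mm",
]


@dataclass(frozen=True)
class RunConfig:
    inputs: tuple[str, ...]
    threshold: ThresholdSpec = ThresholdSpec()
    calibration: CalibrationSpec | None = None
    crop_window: tuple[int, int, int, int] | None = None  # top, left, h, w
    pixel_extent: bool = False
    max_foreground: float = 0.5
    out_dir: str = "."


@dataclass
class RunSummary:
    rows: list[dict] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)

    @property
    def n_analyzed(self) -> int:
        return len(self.rows)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def skipped_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.skipped, columns=["image_id", "reason"])


def measure_mask(mask: np.ndarray, pixel_extent: bool = False) -> DescriptorRecord:
    """Descriptors of the largest 8-connected region of a binary mask."""
    _, regions = label_components(mask)
    region = sort_and_select_largest(regions)
    cs = trace_contours(region, mask)
    hull = convex_hull(region.pixels)
    if pixel_extent:
        hull = with_pixel_extent(hull)
    rect = min_area_rectangle(hull)
    return describe(region, cs, hull, rect, moments(region))


def measure_gray(gray: np.ndarray, spec: ThresholdSpec,
                 pixel_extent: bool = False) -> DescriptorRecord:
    """Threshold a grayscale image and measure its largest region."""
    return measure_mask(threshold(gray, spec), pixel_extent=pixel_extent)


def _record_to_row(image_id: str, cfg: RunConfig, rec: DescriptorRecord,
                   scale: float | None) -> dict:
    row = {"image_id": image_id, "threshold": cfg.threshold.th,
           "polarity": cfg.threshold.polarity}
    row.update(rec.as_dict())
    flags = row.pop("flags")
    if scale is not None:
        si = to_si(rec, scale)
        row.update({
            "F_mm2": si.F, "outer_len_mm": si.outer_len, "total_len_mm": si.total_len,
            "d_max_mm": si.d_max, "ferret_min_mm": si.ferret_min,
            "ferret_max_mm": si.ferret_max, "rect_length_mm": si.rect_length,
            "rect_width_mm": si.rect_width, "Ra_mm": si.Ra, "Rb_mm": si.Rb,
            "fiber_length_mm": si.fiber_length,
        })
    row["flags"] = flags
    return row


def run_pipeline(cfg: RunConfig) -> RunSummary:
    """Process every input image; see module docstring for the chain."""
    paths = imgio.find_images(cfg.inputs)
    if not paths:
        raise ValueError("no inputs")
    scale = resolve_scale(cfg.calibration) if cfg.calibration is not None else None
    summary = RunSummary()
    for path in paths:
        image_id = path.name
        try:
            gray = to_grayscale(imgio.read_image(path))
        except (OSError, ValueError) as exc:
            log.warning("skipping unreadable image %s: %s", path, exc)
            summary.skipped.append({"image_id": image_id, "reason": f"unreadable: {exc}"})
            continue
        if cfg.crop_window is not None:
            gray = crop(gray, *cfg.crop_window)
        report = contrast_report(gray, cfg.threshold, cfg.max_foreground)
        if report.flagged:
            reason = ("no foreground at threshold" if report.foreground_fraction == 0.0
                      else f"foreground fraction {report.foreground_fraction:.3f} "
                           f"exceeds {report.max_fraction}")
            log.warning("skipping %s: %s", path, reason)
            summary.skipped.append({"image_id": image_id, "reason": reason})
            continue
        rec = measure_gray(gray, cfg.threshold, pixel_extent=cfg.pixel_extent)
        summary.rows.append(_record_to_row(image_id, cfg, rec, scale))
    if not summary.rows:
        raise ValueError("all images failed")
    return summary


def write_outputs(summary: RunSummary, out_dir) -> tuple[Path, Path | None]:
    """Write descriptors.csv (6 significant digits) and skipped.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "descriptors.csv"
    summary.frame().to_csv(csv_path, index=False, float_format="%.6g")
    skip_path = None
    if summary.skipped:
        skip_path = out / "skipped.csv"
        summary.skipped_frame().to_csv(skip_path, index=False)
    return csv_path, skip_path


def summarize(table: pd.DataFrame, group_by: str | None = None) -> pd.DataFrame:
    """Per-descriptor mean/min/max/SD table (sample SD, n-1 denominator).

    When ``group_by`` names a column of the table, statistics are computed
    per group; otherwise over all rows.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    numeric = table.select_dtypes(include=[np.number])
    numeric = numeric.drop(columns=[c for c in ("threshold",) if c in numeric], errors="ignore")

    def _stats(df: pd.DataFrame, label) -> list[dict]:
        rows = []
        for col in df.columns:
            vals = df[col].dropna()
            if vals.empty:
                continue
            rows.append({
                **({"group": label} if label is not None else {}),
                "descriptor": col,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            })
        return rows

    rows: list[dict] = []
    if group_by is not None and group_by in table.columns:
        for label, idx in table.groupby(group_by).groups.items():
            rows.extend(_stats(numeric.loc[idx], label))
    else:
        rows.extend(_stats(numeric, None))
    return pd.DataFrame(rows)
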