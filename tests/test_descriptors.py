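import math

import numpy as np
import pytest

from conftest import largest_region
from mpshape.contours import trace_contours
from mpshape.descriptors import (
    FLAG_DEGENERATE_WIDTH,
    FLAG_SINGLE_PIXEL,
    MomentSet,
    area,
    circularity,
    d_max,
    ellipse_axes,
    elongatedness,
    fiber_length,
    moments,
)
from mpshape.geometry import RectangleFit
from mpshape.pipeline import measure_mask
from mpshape.synthetic import ShapeSpec, rasterize
from oracles import boundary_pixels


def disk_mask(radius, pad=4):
    n = int(2 * radius) + 2 * pad
    mask, _ = rasterize(ShapeSpec("disk", radius=radius), n, n)
    return mask


class TestArea:
    def test_block(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[1:4, 1:4] = 1
        assert area(largest_region(mask)) == 9

    def test_single_pixel(self, single_pixel):
        assert area(largest_region(single_pixel)) == 1

    def test_disk_close_to_analytic(self):
        f = area(largest_region(disk_mask(20)))
        assert f == pytest.approx(math.pi * 400, rel=0.02)


class TestMoments:
    def test_single_pixel_zero(self, single_pixel):
        m = moments(largest_region(single_pixel))
        assert (m.M11, m.M20, m.M02) == (0.0, 0.0, 0.0)

    def test_1x3_horizontal_line(self):
        mask = np.zeros((3, 5), dtype=np.uint8)
        mask[1, 1:4] = 1
        m = moments(largest_region(mask))
        assert m.M02 == pytest.approx(2.0 / 3.0)
        assert m.M20 == 0.0
        assert m.M11 == 0.0

    def test_symmetric_shapes_m11_zero(self):
        m = moments(largest_region(disk_mask(10)))
        assert m.M11 == pytest.approx(0.0, abs=1e-9)
        sq = np.zeros((8, 8), dtype=np.uint8)
        sq[1:7, 1:7] = 1
        assert moments(largest_region(sq)).M11 == pytest.approx(0.0, abs=1e-12)

    def test_cauchy_schwarz(self):
        rng = np.random.default_rng(4)
        blob = np.zeros((20, 20), dtype=np.uint8)
        blob[3:17, 3:17] = (rng.random((14, 14)) < 0.6).astype(np.uint8)
        blob[8:12, 8:12] = 1
        m = moments(largest_region(blob))
        assert m.M11 ** 2 <= m.M20 * m.M02 + 1e-12


class TestEllipseAxes:
    def test_single_pixel(self):
        assert ellipse_axes(MomentSet(0.0, 0.0, 0.0)) == (0.0, 0.0)

    def test_disk_recovers_radius(self):
        ra, rb = ellipse_axes(moments(largest_region(disk_mask(20))))
        assert ra == pytest.approx(20, rel=0.03)
        assert rb == pytest.approx(20, rel=0.03)

    @pytest.mark.parametrize("angle", [0.0, 30.0, 77.5, 120.0])
    def test_rotated_ellipse_recovery(self, angle):
        mask, _ = rasterize(
            ShapeSpec("ellipse", semi_axes=(40.0, 10.0), angle_deg=angle), 96, 96
        )
        ra, rb = ellipse_axes(moments(largest_region(mask)))
        assert ra == pytest.approx(40.0, rel=0.03)
        assert rb == pytest.approx(10.0, rel=0.03)

    def test_ra_ge_rb(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            m20, m02 = rng.uniform(0, 50, 2)
            m11 = rng.uniform(-1, 1) * math.sqrt(m20 * m02)
            ra, rb = ellipse_axes(MomentSet(m11, m20, m02))
            assert ra >= rb >= 0.0


class TestDMax:
    def test_single_pixel(self, single_pixel):
        region = largest_region(single_pixel)
        assert d_max(region, trace_contours(region, single_pixel)) == 0.0

    def test_2x2_block(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[1:3, 1:3] = 1
        region = largest_region(mask)
        assert d_max(region, trace_contours(region, mask)) == pytest.approx(math.sqrt(0.5))

    def test_equals_brute_force_over_boundary(self, annulus):
        region = largest_region(annulus)
        cs = trace_contours(region, annulus)
        r0, c0 = region.centroid
        rmask = region.to_mask(annulus.shape)
        brute = max(math.hypot(r - r0, c - c0) for r, c in boundary_pixels(rmask))
        assert d_max(region, cs) == pytest.approx(brute)


class TestCircularity:
    def test_disk_near_one(self):
        mask = disk_mask(64)
        region = largest_region(mask)
        cs = trace_contours(region, mask)
        raw = circularity(region.area, d_max(region, cs), clamp=False)
        assert raw == pytest.approx(1.0, rel=0.02)

    def test_bar_below_one(self):
        mask = np.zeros((9, 306), dtype=np.uint8)
        mask[3:6, 3:303] = 1
        assert measure_mask(mask).circularity < 1.0

    def test_single_pixel_clamped(self):
        assert circularity(1, 0.0) == 1.0

    def test_clamp_bounds(self):
        assert circularity(100, 1.0, clamp=True) == 1.0
        assert circularity(100, 1.0, clamp=False) > 1.0


class TestCompactness:
    def test_disk_near_one(self):
        rec = measure_mask(disk_mask(64))
        assert rec.compactness == pytest.approx(1.0, rel=0.15)

    def test_bar_above_one(self):
        mask = np.zeros((9, 306), dtype=np.uint8)
        mask[3:6, 3:303] = 1
        assert measure_mask(mask).compactness > 1.0

    def test_hole_increases_compactness(self, block_5x5, block_5x5_hole):
        assert measure_mask(block_5x5_hole).compactness > measure_mask(block_5x5).compactness

    def test_single_pixel_zero(self, single_pixel):
        rec = measure_mask(single_pixel)
        assert rec.compactness == 0.0 and FLAG_SINGLE_PIXEL in rec.flags


class TestElongatedness:
    def test_square_is_one(self):
        mask = np.zeros((12, 12), dtype=np.uint8)
        mask[1:11, 1:11] = 1
        assert measure_mask(mask).elongatedness == pytest.approx(1.0)

    def test_3x20_block(self):
        mask = np.zeros((5, 22), dtype=np.uint8)
        mask[1:4, 1:21] = 1
        assert measure_mask(mask).elongatedness == pytest.approx(19.0 / 2.0)

    def test_line_degenerate(self):
        mask = np.zeros((3, 10), dtype=np.uint8)
        mask[1, 1:9] = 1
        rec = measure_mask(mask)
        assert math.isnan(rec.elongatedness)
        assert FLAG_DEGENERATE_WIDTH in rec.flags

    def test_ge_one_when_width_positive(self):
        rect = RectangleFit(center=(0, 0), length=5.0, width=2.0, angle=10.0)
        assert elongatedness(rect) >= 1.0


class TestFiberLength:
    def test_half_outer(self):
        assert fiber_length(198.0) == 99.0

    def test_zero(self):
        assert fiber_length(0.0) == 0.0

    def test_1x100_line(self):
        mask = np.zeros((3, 102), dtype=np.uint8)
        mask[1, 1:101] = 1
        rec = measure_mask(mask)
        assert rec.outer_len == pytest.approx(198.0)
        assert rec.fiber_length == pytest.approx(99.0)

    def test_3x100_overestimates(self):
        spec = ShapeSpec("fiber", centerline=((10.0, 5.0), (10.0, 105.0)), width=3.0)
        mask, truth = rasterize(spec, 21, 120)
        rec = measure_mask(mask)
        assert rec.fiber_length >= truth.true_fiber_length
        assert rec.fiber_length <= truth.true_fiber_length + 3.0 + 2.0


class TestDescribe:
    def test_disk_record(self):
        rec = measure_mask(disk_mask(40))
        assert rec.circularity == pytest.approx(1.0, rel=0.03)
        assert rec.compactness == pytest.approx(1.0, rel=0.15)
        assert rec.elongatedness == pytest.approx(1.0, rel=0.05)

    def test_fiber_record(self):
        spec = ShapeSpec("fiber", centerline=((20.0, 10.0), (20.0, 160.0)), width=3.0)
        mask, _ = rasterize(spec, 40, 180)
        rec = measure_mask(mask)
        assert rec.circularity < 0.2
        assert rec.compactness > 5.0

    def test_max_ferret_bounds_semi_axes(self):
        for mask in (disk_mask(20), rasterize(
                ShapeSpec("ellipse", semi_axes=(30.0, 12.0), angle_deg=25.0), 80, 80)[0]):
            rec = measure_mask(mask)
            assert rec.ferret_max >= rec.Ra >= rec.Rb

    def test_translation_invariance(self, annulus):
        base = measure_mask(annulus)
        shifted = measure_mask(np.pad(annulus, ((7, 0), (0, 9))))
        for name in ("F", "outer_len", "total_len", "d_max", "circularity",
                     "compactness", "ferret_min", "ferret_max", "rect_length",
                     "rect_width", "elongatedness", "Ra", "Rb", "fiber_length"):
            a, b = getattr(base, name), getattr(shifted, name)
            assert a == pytest.approx(b), name

    def test_rot90_exact_invariants(self):
        mask, _ = rasterize(ShapeSpec("ellipse", semi_axes=(20.0, 9.0), angle_deg=33.0), 60, 60)
        base = measure_mask(mask)
        rot = measure_mask(np.rot90(mask).copy())
        assert rot.F == base.F
        assert rot.circularity == pytest.approx(base.circularity)
        assert rot.compactness == pytest.approx(base.compactness)
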