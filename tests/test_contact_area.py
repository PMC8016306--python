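"""Ink-image contact-area quantification."""

import numpy as np
import pytest

from tactillusion.contact_area import (
    ContactOutline,
    InkImage,
    measure_contact_area,
    pixel_scale,
    polygon_area,
    threshold_contact_region,
    trace_outline,
)
from tactillusion.synthetic_data import gen_ink_image


def _blank(h=120, w=120):
    return np.full((h, w, 3), 245, dtype=np.uint8)


def _with_disk(img, cx, cy, r, color=(40, 45, 120)):
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = color
    return img


class TestPixelScale:
    @pytest.mark.parametrize("bar_px,expected", [(500, 0.01), (250, 0.02)])
    def test_bar_division(self, bar_px, expected):
        img = InkImage(raster=_blank(), bar_pixels=bar_px, bar_length=5.0)
        assert pixel_scale(img) == pytest.approx(expected)

    def test_zero_bar_rejected(self):
        img = InkImage(raster=_blank(), bar_pixels=0)
        with pytest.raises(ValueError):
            pixel_scale(img)

    def test_autodetection_from_drawn_bar(self):
        raster = _blank(100, 400)
        raster[10:14, 50:350] = (30, 30, 30)
        img = InkImage(raster=raster, bar_pixels=None)
        assert pixel_scale(img) == pytest.approx(5.0 / 300, rel=0.02)


class TestThreshold:
    def test_disk_inside_roi_recovered(self):
        img = InkImage(_with_disk(_blank(), 60, 60, 20))
        mask = threshold_contact_region(img, (60, 60), 40)
        yy, xx = np.mgrid[0:120, 0:120]
        truth = (xx - 60) ** 2 + (yy - 60) ** 2 <= 400
        assert (mask & truth).sum() / truth.sum() > 0.99

    def test_disk_outside_roi_excluded(self):
        img = InkImage(_with_disk(_blank(), 100, 100, 15))
        with pytest.warns(UserWarning):
            mask = threshold_contact_region(img, (30, 30), 25)
        assert not mask.any()

    def test_speckled_disk_cleaned(self):
        rng = np.random.default_rng(0)
        raster = _with_disk(_blank(), 60, 60, 25)
        # pepper the disk with white pinholes and the paper with dark dots
        ys = rng.integers(0, 120, 80)
        xs = rng.integers(0, 120, 80)
        raster[ys[:40], xs[:40]] = (250, 250, 250)
        raster[ys[40:], xs[40:]] = (60, 60, 90)
        mask = threshold_contact_region(InkImage(raster), (60, 60), 40)
        yy, xx = np.mgrid[0:120, 0:120]
        truth = (xx - 60) ** 2 + (yy - 60) ** 2 <= 625
        assert (mask & truth).sum() / truth.sum() >= 0.99

    def test_roi_center_outside_raster_rejected(self):
        with pytest.raises(ValueError):
            threshold_contact_region(InkImage(_blank()), (500, 500), 10)


class TestTraceOutline:
    def test_filled_square_gives_four_corners(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        outline = trace_outline(mask)
        assert len(outline.polygon) == 4
        assert polygon_area(outline) == pytest.approx(100.0)

    def test_largest_of_two_components_with_warning(self):
        mask = np.zeros((30, 30), bool)
        mask[2:6, 2:6] = True  # 16 px
        mask[10:25, 10:25] = True  # 225 px
        with pytest.warns(UserWarning):
            outline = trace_outline(mask)
        assert polygon_area(outline) == pytest.approx(225.0)

    def test_disk_area_within_2pct(self):
        yy, xx = np.mgrid[0:200, 0:200]
        mask = (xx - 100) ** 2 + (yy - 100) ** 2 <= 80**2
        outline = trace_outline(mask)
        assert polygon_area(outline) == pytest.approx(np.pi * 80**2, rel=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            trace_outline(np.zeros((10, 10), bool))


class TestPolygonArea:
    def test_unit_square(self):
        sq = ContactOutline(np.array([[0, 0], [1, 0], [1, 1], [0, 1]]), 1.0)
        assert polygon_area(sq) == pytest.approx(1.0)

    def test_right_triangle_closed_form(self):
        tri = ContactOutline(np.array([[0, 0], [4, 0], [0, 3]]), 1.0)
        assert polygon_area(tri) == pytest.approx(6.0)

    def test_rasterized_disk_within_1pct(self):
        yy, xx = np.mgrid[0:260, 0:260]
        mask = (xx - 130) ** 2 + (yy - 130) ** 2 <= 100**2
        outline = trace_outline(mask, scale=0.01)
        assert polygon_area(outline) == pytest.approx(np.pi * 1.0**2, rel=0.01)

    def test_invariance_to_rotation_and_reversal(self):
        pts = np.array([[0, 0], [4, 0], [5, 3], [1, 5]], float)
        base = polygon_area(ContactOutline(pts, 1.0))
        rolled = polygon_area(ContactOutline(np.roll(pts, 2, axis=0), 1.0))
        reversed_ = polygon_area(ContactOutline(pts[::-1], 1.0))
        assert base == pytest.approx(rolled) == pytest.approx(reversed_)

    def test_quadratic_scale_dependence(self):
        pts = np.array([[0, 0], [4, 0], [4, 4], [0, 4]], float)
        a1 = polygon_area(ContactOutline(pts, 1.0))
        a2 = polygon_area(ContactOutline(pts, 2.0))
        assert a2 == pytest.approx(4.0 * a1)

    def test_degenerate_polygons_rejected(self):
        with pytest.raises(ValueError):
            ContactOutline(np.array([[0, 0], [1, 1]]), 1.0)
        bowtie = ContactOutline(np.array([[0, 0], [2, 2], [2, 0], [0, 2]]), 1.0)
        with pytest.raises(ValueError):
            polygon_area(bowtie)


class TestEndToEnd:
    @pytest.mark.parametrize("area", [0.5, 1.0, 1.5, 2.0])
    def test_known_area_recovered_within_3pct(self, area):
        image, truth = gen_ink_image(area, scale_cm_per_px=0.01, seed=int(area * 10))
        est = measure_contact_area(image, truth["roi_center"], truth["roi_radius"])
        assert est == pytest.approx(area, rel=0.03)

    def test_noiseless_fixture_within_1pct(self):
        image, truth = gen_ink_image(1.0, scale_cm_per_px=0.01,
                                     speckle_fraction=0.0, seed=3)
        est = measure_contact_area(image, truth["roi_center"], truth["roi_radius"])
        assert est == pytest.approx(truth["area_cm2"], rel=0.01)
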