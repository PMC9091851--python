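"""Sector/quadrant polygon construction and raster measurement."""

import numpy as np
import pytest

from rppkit import (
    GeometryError,
    LabelImage,
    SectorSpec,
    build_quadrants,
    measure_quadrant,
    measure_section,
    place_sectors_auto,
)
from rppkit.geometry import CLASS_PRIMARY, CLASS_REMODELLED, CLASS_VASCULAR


def annulus_sector(r_in, r_out, angle0_deg, angle1_deg, n=64, center=(0.0, 0.0)):
    """Exact annulus sector: circular-arc borders, straight radial sides."""
    ang = np.radians(np.linspace(angle0_deg, angle1_deg, n))
    cx, cy = center
    inner = np.column_stack([cx + r_in * np.cos(ang), cy + r_in * np.sin(ang)])
    outer = np.column_stack([cx + r_out * np.cos(ang), cy + r_out * np.sin(ang)])
    side1 = np.vstack([inner[0], outer[0]])
    side2 = np.vstack([inner[-1], outer[-1]])
    return SectorSpec(1, inner, outer, side1, side2)


def rect_sector(width, height):
    inner = np.array([[0.0, 0.0], [width, 0.0]])
    outer = np.array([[0.0, height], [width, height]])
    side1 = np.array([[0.0, 0.0], [0.0, height]])
    side2 = np.array([[width, 0.0], [width, height]])
    return SectorSpec(1, inner, outer, side1, side2)


class TestBuildQuadrants:
    def test_rectangular_sector_gives_congruent_slabs(self):
        quads = build_quadrants(rect_sector(30.0, 40.0))
        areas = [q.area for q in quads]
        assert areas == pytest.approx([300.0] * 4, rel=1e-9)
        # a adjacent to the inner boundary (y = 0)
        assert quads[0].polygon.centroid.y < quads[3].polygon.centroid.y

    def test_annulus_quadrants_equal_radial_width(self):
        quads = build_quadrants(annulus_sector(50, 150, 0, 60))
        # closed-form annulus-sector areas for radial spans of width 25
        spans = [(50, 75), (75, 100), (100, 125), (125, 150)]
        frac = np.radians(60) / 2.0
        for q, (a, b) in zip(quads, spans):
            assert q.area == pytest.approx(frac * (b**2 - a**2), rel=2e-3)
        areas = [q.area for q in quads]
        assert areas == sorted(areas)  # inner quadrants are smaller
        assert areas[3] / areas[0] == pytest.approx(6875 / 3125, rel=5e-3)

    def test_quadrants_partition_sector(self):
        sector = annulus_sector(40, 120, 20, 110)
        quads = build_quadrants(sector)
        total = sum(q.area for q in quads)
        assert total == pytest.approx(sector.polygon().area, rel=1e-9)

    def test_order_contract_flipped_input_polylines(self):
        # reversing the vertex order of every polyline must not change which
        # quadrant touches the inner boundary
        ang = np.radians(np.linspace(0, 60, 64))
        inner = np.column_stack([50 * np.cos(ang), 50 * np.sin(ang)])
        outer = np.column_stack([150 * np.cos(ang), 150 * np.sin(ang)])
        side1 = np.vstack([inner[0], outer[0]])
        side2 = np.vstack([inner[-1], outer[-1]])
        flipped = SectorSpec(
            1, inner[::-1], outer[::-1], side1[::-1], side2[::-1]
        )
        quads = build_quadrants(flipped)
        r_a = np.hypot(quads[0].polygon.centroid.x, quads[0].polygon.centroid.y)
        r_d = np.hypot(quads[3].polygon.centroid.x, quads[3].polygon.centroid.y)
        assert r_a < r_d

    def test_non_closing_polylines_rejected(self):
        with pytest.raises(GeometryError):
            SectorSpec(
                1,
                np.array([[0.0, 0.0], [10.0, 0.0]]),
                np.array([[0.0, 20.0], [10.0, 20.0]]),
                np.array([[500.0, 500.0], [501.0, 501.0]]),  # nowhere near
                np.array([[10.0, 0.0], [10.0, 20.0]]),
            )


class TestMeasureQuadrant:
    def make_image(self, fill=CLASS_PRIMARY, size=80):
        return LabelImage(np.full((size, size), fill, dtype=np.uint8))

    def square_quadrant(self, x0=9.5, y0=9.5, w=40, h=10):
        # half-integer bounds put polygon edges between pixel centres
        from rppkit.geometry import QuadrantGeometry
        from shapely.geometry import box

        return QuadrantGeometry(1, "a", box(x0, y0, x0 + w, y0 + h))

    def test_all_primary_is_zero_porosity(self):
        m = measure_quadrant(self.make_image(), self.square_quadrant())
        assert m.porosity == pytest.approx(0.0)

    def test_checkerboard_is_half_porous(self):
        img = np.full((80, 80), CLASS_PRIMARY, dtype=np.uint8)
        img[(np.indices((80, 80)).sum(axis=0) % 2) == 0] = CLASS_VASCULAR
        m = measure_quadrant(LabelImage(img), self.square_quadrant())
        assert m.porosity == pytest.approx(50.0, abs=1.0)

    def test_mostly_remodelled_quadrant_goes_missing(self):
        img = np.full((80, 80), CLASS_PRIMARY, dtype=np.uint8)
        img[:, :45] = CLASS_REMODELLED  # ~60% of a quadrant spanning x 10..50
        m = measure_quadrant(LabelImage(img), self.square_quadrant())
        assert m.porosity is None
        assert "remodelled" in m.exclusion_classes

    def test_exclusion_shrinks_denominator(self):
        img = np.full((80, 80), CLASS_PRIMARY, dtype=np.uint8)
        img[:, 10:20] = CLASS_REMODELLED  # 25% of quadrant
        img[:, 20:30] = CLASS_VASCULAR  # 25% of quadrant
        m = measure_quadrant(LabelImage(img), self.square_quadrant())
        # porosity = vascular / (area - remodelled) = 25 / 75
        assert m.porosity == pytest.approx(100 * 25 / 75, abs=1.0)

    def test_polygon_outside_raster_rejected(self):
        from rppkit.geometry import QuadrantGeometry
        from shapely.geometry import box

        q = QuadrantGeometry(1, "a", box(70, 70, 120, 120))
        with pytest.raises(GeometryError):
            measure_quadrant(self.make_image(size=80), q)


class TestMeasureSection:
    def test_all_compact_section(self):
        from rppkit import SectionBlueprint, generate_section

        bp = SectionBlueprint(
            cavity_radius=40,
            cortex_thickness=60,
            radial_porosity_function=lambda d: np.zeros_like(np.asarray(d, float)),
            seed=0,
        )
        img, _ = generate_section(bp)
        sectors = place_sectors_auto(img, 3)
        profiles, layers = measure_section(img, sectors)
        for p in profiles:
            assert p.values == pytest.approx((0, 0, 0, 0))
        assert {l.layer: l.relative_area_percent for l in layers} == {
            "OCL": 0.0,
            "EL": 0.0,
        }

    def test_el_annulus_thickness_recovered(self):
        from rppkit import SectionBlueprint, generate_section

        bp = SectionBlueprint(el_fraction=0.1, seed=3)
        img, _ = generate_section(bp)
        sectors = place_sectors_auto(img, 3)
        _, layers = measure_section(img, sectors)
        el = {l.layer: l.relative_area_percent for l in layers}["EL"]
        # EL occupies the innermost 10% of cortex thickness; its area share
        # of the annulus (r0=80, t=160) is (96^2-80^2)/(240^2-80^2) = 5.5%
        assert el == pytest.approx(100 * (96**2 - 80**2) / (240**2 - 80**2), abs=0.5)

    def test_rotation_equivariance(self):
        from rppkit import SectionBlueprint, generate_section
        from rppkit.core import mean_rpp

        bp = SectionBlueprint(
            radial_porosity_function=lambda d: 0.35 - 0.2 * np.asarray(d), seed=9
        )
        img, _ = generate_section(bp)
        rotated = LabelImage(np.rot90(img.raster).copy(), img.pixel_size)
        base = measure_section(img, place_sectors_auto(img, 3, [15, 135, 255]))[0]
        # np.rot90 maps the ray at angle theta to theta - 90 degrees
        rot = measure_section(
            rotated, place_sectors_auto(rotated, 3, [-75, 45, 165])
        )[0]
        m1 = mean_rpp(base).as_array()
        m2 = mean_rpp(rot).as_array()
        assert np.allclose(m1, m2, atol=1.0)

    def test_resolution_convergence(self):
        # porosity error shrinks when the section is rendered at doubled
        # linear resolution (quadrupled pixel count)
        from rppkit import SectionBlueprint, generate_section
        from rppkit.core import mean_rpp

        errs = []
        for scale in (0.5, 1.0):
            bp = SectionBlueprint(
                cavity_radius=80 * scale,
                cortex_thickness=160 * scale,
                pore_radius_mean=2.5 * scale,
                pore_radius_sd=0.6 * scale,
                radial_porosity_function=lambda d: np.full_like(
                    np.asarray(d, float), 0.3
                ),
                seed=4,
            )
            img, gt = generate_section(bp)
            profiles, _ = measure_section(img, place_sectors_auto(img, 3))
            m = mean_rpp(profiles).as_array()
            errs.append(np.abs(m - gt.quadrant_target_percent).mean())
        assert errs[1] < errs[0]


class TestPlaceSectorsAuto:
    def test_congruent_sectors_on_perfect_annulus(self):
        from rppkit import SectionBlueprint, generate_section

        bp = SectionBlueprint(
            radial_porosity_function=lambda d: np.zeros_like(np.asarray(d, float)),
            seed=0,
        )
        img, _ = generate_section(bp)
        sectors = place_sectors_auto(img, 3, [0, 120, 240])
        areas = [s.polygon().area for s in sectors]
        assert max(areas) - min(areas) < 0.01 * np.mean(areas)

    def test_single_sector(self):
        from rppkit import SectionBlueprint, generate_section

        bp = SectionBlueprint(seed=1)
        img, _ = generate_section(bp)
        (sector,) = place_sectors_auto(img, 1, [90])
        assert sector.polygon().is_valid

    def test_off_center_cavity_still_valid(self):
        size = 300
        yy, xx = np.mgrid[0:size, 0:size]
        rr_ring = np.hypot(xx - 150, yy - 150)
        rr_cav = np.hypot(xx - 170, yy - 150)  # cavity shifted off-centre
        img = np.zeros((size, size), dtype=np.uint8)
        img[rr_ring < 120] = 1
        img[rr_cav < 40] = 3
        sectors = place_sectors_auto(LabelImage(img), 3)
        side_lengths = []
        for s in sectors:
            assert s.polygon().is_valid
            side_lengths.append(
                np.linalg.norm(s.radial_side_1[-1] - s.radial_side_1[0])
            )
        assert len(set(np.round(side_lengths, 1))) > 1  # unequal radial sides

    def test_broken_ring_raises(self):
        img = np.zeros((200, 200), dtype=np.uint8)
        yy, xx = np.mgrid[0:200, 0:200]
        rr = np.hypot(xx - 100, yy - 100)
        img[rr < 30] = 3
        ring = (rr >= 30) & (rr < 70) & (xx > 100)  # half-ring only
        img[ring] = 1
        with pytest.raises(GeometryError):
            place_sectors_auto(LabelImage(img), 1, [180])
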