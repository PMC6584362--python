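"""Per-cell and per-plate morphometrics against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely import contains_xy
from shapely.geometry import Polygon
from skimage import measure

from ovimorph import (
    CellPolygon,
    GeometryError,
    ParameterError,
    PlateSpec,
    TissuePlate,
    cell_density,
    cell_metrics,
    classify_alignment,
    corrected_total_count,
    fit_ellipse,
    generate_hex_plate,
    polygon_area,
    summarize_plate,
    transect_counts,
)
from conftest import random_convex_polygon


class TestPolygonArea:
    @pytest.mark.parametrize("verts,expected", [
        ([[0, 0], [1, 0], [1, 1], [0, 1]], 1.0),
        ([[0, 0], [2, 0], [0, 2]], 2.0),
        ([[0, 0], [0, 2], [2, 0]], 2.0),  # reversed orientation
    ])
    def test_known_shapes(self, verts, expected):
        assert polygon_area(CellPolygon(1, np.array(verts, float))) == pytest.approx(expected)

    def test_matches_monte_carlo_oracle(self):
        """Rejection-sampling area of a random convex 12-gon within 1%."""
        rng = np.random.default_rng(11)
        verts = random_convex_polygon(rng)
        poly = Polygon(verts)
        xmin, ymin, xmax, ymax = poly.bounds
        n = 10**6
        pts_x = rng.uniform(xmin, xmax, n)
        pts_y = rng.uniform(ymin, ymax, n)
        frac = contains_xy(poly, pts_x, pts_y).mean()
        mc_area = frac * (xmax - xmin) * (ymax - ymin)
        assert polygon_area(CellPolygon(1, verts)) == pytest.approx(mc_area, rel=0.01)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(GeometryError):
            polygon_area(CellPolygon(1, np.array([[0, 0], [1, 1], [2, 2]], float)))


class TestFitEllipse:
    def test_circle_is_isotropic(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        circle = CellPolygon(1, np.column_stack([np.cos(t), np.sin(t)]))
        l1, l2, _ = fit_ellipse(circle)
        assert l2 / l1 == pytest.approx(1.0, abs=0.01)
        # moment ellipse of a near-circle recovers the diameter
        assert l2 == pytest.approx(2.0, rel=0.01)

    def test_rectangle_axis_ratio_and_orientation(self):
        """w=1, h=2 rectangle: closed-form moments give ratio h/w, long axis
        90 degrees from the width axis."""
        rect = CellPolygon(1, np.array([[0, 0], [1, 0], [1, 2], [0, 2]], float))
        l1, l2, theta = fit_ellipse(rect)
        assert l2 / l1 == pytest.approx(2.0, rel=1e-9)
        assert theta == pytest.approx(90.0, abs=1e-9)

    @pytest.mark.parametrize("delta", [17.0, 61.5, 120.0, 179.0])
    def test_rotation_equivariance(self, delta):
        rng = np.random.default_rng(5)
        verts = random_convex_polygon(rng)
        l1a, l2a, tha = fit_ellipse(CellPolygon(1, verts))
        rad = math.radians(delta)
        rot = np.array([[math.cos(rad), -math.sin(rad)],
                        [math.sin(rad), math.cos(rad)]])
        l1b, l2b, thb = fit_ellipse(CellPolygon(1, verts @ rot.T))
        assert l1b == pytest.approx(l1a, abs=1e-9)
        assert l2b == pytest.approx(l2a, abs=1e-9)
        assert thb == pytest.approx((tha + delta) % 180.0, abs=1e-6)

    def test_agrees_with_raster_second_moment_oracle(self):
        """Exact interior moments vs pixel second moments (regionprops) on
        random convex polygons: axes within 1%."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            verts = random_convex_polygon(rng)
            l1, l2, _ = fit_ellipse(CellPolygon(1, verts))
            poly = Polygon(verts)
            xmin, ymin, xmax, ymax = poly.bounds
            px = max(xmax - xmin, ymax - ymin) / 500
            xs = np.arange(xmin - 2 * px, xmax + 2 * px, px)
            ys = np.arange(ymin - 2 * px, ymax + 2 * px, px)
            xx, yy = np.meshgrid(xs, ys)
            lbl = contains_xy(poly, xx, yy).astype(int)
            props = measure.regionprops(lbl)[0]
            assert props.axis_minor_length * px == pytest.approx(l1, rel=0.01)
            assert props.axis_major_length * px == pytest.approx(l2, rel=0.01)


class TestAlignment:
    @pytest.mark.parametrize("theta,expected", [
        (10.0, True),
        (44.999, True),
        (45.0, False),  # boundary is non-aligned
        (90.0, False),
        (135.0, False),
        (135.001, True),
        (170.0, True),  # acute angle 10
    ])
    def test_rule(self, theta, expected):
        assert classify_alignment(theta) is expected

    @given(st.floats(0, 179.999), st.integers(-3, 3))
    @settings(derandomize=True, max_examples=50)
    def test_axial_wrap(self, theta, k):
        assert classify_alignment(theta) == classify_alignment(theta + 180.0 * k)


class TestCorrectedCount:
    @pytest.mark.parametrize("n,seg,total,expected", [
        (100, 50.0, 50.0, 100.0),
        (90, 45.0, 50.0, 100.0),
    ])
    def test_examples(self, n, seg, total, expected):
        assert corrected_total_count(n, seg, total) == pytest.approx(expected)

    def test_paper_scale_one_percent_missing(self):
        seg = 1000.0
        total = seg / 0.99
        assert round(corrected_total_count(1600, seg, total)) == 1616

    def test_monotone_in_total_area(self):
        counts = [corrected_total_count(500, 100.0, total)
                  for total in (100.0, 110.0, 125.0, 150.0)]
        assert counts == sorted(counts) and counts[0] == 500.0

    def test_rejects_total_below_segmented(self):
        with pytest.raises(ParameterError):
            corrected_total_count(10, 50.0, 49.0)


class TestTransects:
    def test_grid_rows_and_columns(self, grid_plate):
        assert transect_counts(grid_plate, "row") == pytest.approx(10.0)
        assert transect_counts(grid_plate, "column") == pytest.approx(5.0)

    def test_hex_plate_recovers_lattice_counts(self):
        plate = generate_hex_plate(PlateSpec(45, 29, 11.68, 1.57, 0.52, 3.0, seed=1))
        assert transect_counts(plate, "row") == pytest.approx(45.0, abs=1.0)
        assert transect_counts(plate, "column") == pytest.approx(29.0, abs=1.0)

    def test_rejects_bad_fractions(self, grid_plate):
        with pytest.raises(ParameterError):
            transect_counts(grid_plate, "row", fractions=(0.0, 0.5, 1.2))


class TestSummarize:
    def test_single_cell_plate(self, unit_square):
        summary = summarize_plate(TissuePlate(cells=(unit_square,)))
        assert summary.n_total == 1
        assert summary.anisotropy == pytest.approx(1.0)

    def test_square_plate_is_isotropic(self):
        plate = generate_hex_plate(PlateSpec(12, 12, 2.0, seed=3))
        summary = summarize_plate(plate)
        assert summary.anisotropy == pytest.approx(1.0, abs=0.05)

    def test_round_trip_at_study_parameters(self):
        """Generated 45 x 29 plate at the 54 h APF D. melanogaster values:
        measurement recovers area within 2%, shape within 5%, sigma within
        10%."""
        plate = generate_hex_plate(PlateSpec(45, 29, 11.68, 1.57, 0.52, 3.0, seed=0))
        summary = summarize_plate(plate)
        assert summary.mean_area == pytest.approx(11.68, rel=0.02)
        assert summary.mean_shape == pytest.approx(1.57, rel=0.05)
        assert summary.anisotropy == pytest.approx(45 / 29, rel=0.10)
        assert summary.n_total == pytest.approx(45 * 29)

    def test_rotation_equivariance(self, small_hex_plate):
        """Rotating plate and PD axis together leaves the summary unchanged."""
        base = summarize_plate(small_hex_plate)
        rad = math.radians(33.0)
        rot = np.array([[math.cos(rad), -math.sin(rad)],
                        [math.sin(rad), math.cos(rad)]])
        rotated = TissuePlate(
            cells=tuple(CellPolygon(c.cell_id, c.vertices @ rot.T)
                        for c in small_hex_plate.cells),
            pd_axis=rot @ np.array(small_hex_plate.pd_axis),
        )
        other = summarize_plate(rotated)
        for name in ("n_total", "cells_per_row", "cells_per_column",
                     "anisotropy", "mean_area", "mean_shape", "aligned_fraction"):
            assert getattr(other, name) == pytest.approx(
                getattr(base, name), rel=1e-6)


class TestScaleEquivariance:
    @given(st.floats(0.1, 10.0))
    @settings(derandomize=True, max_examples=25)
    def test_cell_metrics_scale(self, c):
        rng = np.random.default_rng(2)
        verts = random_convex_polygon(rng)
        m0 = cell_metrics(CellPolygon(1, verts))
        m1 = cell_metrics(CellPolygon(1, verts * c))
        assert m1.area == pytest.approx(m0.area * c * c, rel=1e-9)
        assert m1.long_axis == pytest.approx(m0.long_axis * c, rel=1e-9)
        assert m1.shape_ratio == pytest.approx(m0.shape_ratio, rel=1e-9)
        assert m1.orientation == pytest.approx(m0.orientation, abs=1e-6)


class TestDensity:
    def test_ratio_and_inverse(self):
        assert cell_density(50, 25.0) == pytest.approx(2.0)
        assert cell_density(0, 10.0) == 0.0
        d = cell_density(123, 45.6)
        assert d * 45.6 == pytest.approx(123.0)

    def test_rejects_nonpositive_area(self):
        with pytest.raises(ParameterError):
            cell_density(5, 0.0)
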