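"""Ground-truth generators: determinism, tiling exactness, recovery."""

from dataclasses import replace

import numpy as np
import pytest
from shapely.geometry import Polygon
from shapely.ops import unary_union

from ovimorph import (
    GeometryError,
    GrowthPhase,
    GrowthSchedule,
    ParameterError,
    PlateSpec,
    T1Script,
    detect_t1_events,
    generate_allometry_dataset,
    generate_growth_series,
    generate_hex_plate,
    generate_tracked_series,
    polygon_area,
    rasterize_plate,
    sma_fit,
    summarize_plate,
)


class TestPlateSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(n_per_row=0, m_per_column=3),
        dict(n_per_row=3, m_per_column=3, cell_area=-1.0),
        dict(n_per_row=3, m_per_column=3, shape_ratio=0.8),
        dict(n_per_row=3, m_per_column=3, aligned_fraction=1.2),
        dict(n_per_row=3, m_per_column=3, orientation_noise=-1.0),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            PlateSpec(**kwargs)


class TestHexPlate:
    def test_regular_tiling_example(self):
        """3 x 3, unit area, s = 1, no noise: nine regular hexagons."""
        plate = generate_hex_plate(PlateSpec(3, 3, 1.0, 1.0, 1.0, 0.0, seed=0))
        assert plate.n_cells == 9
        assert plate.segmented_area == pytest.approx(9.0, rel=1e-9)
        for cell in plate.cells:
            assert len(cell.vertices) == 6
            assert polygon_area(cell) == pytest.approx(1.0, rel=1e-9)

    def test_determinism(self):
        spec = PlateSpec(8, 6, 2.5, 1.4, 0.5, 4.0, seed=123)
        a = generate_hex_plate(spec)
        b = generate_hex_plate(spec)
        for ca, cb in zip(a.cells, b.cells):
            assert ca.cell_id == cb.cell_id
            np.testing.assert_array_equal(ca.vertices, cb.vertices)

    @pytest.mark.parametrize("noise", [0.0, 4.0])
    def test_tiling_is_exact(self, noise):
        """Cells are interior-disjoint and cover the plate footprint: the
        union area equals the summed cell area within 0.5% (here ~1e-9),
        and the footprint has no holes."""
        plate = generate_hex_plate(PlateSpec(9, 7, 3.0, 1.5, 0.5, noise, seed=2))
        polys = [Polygon(c.vertices) for c in plate.cells]
        union = unary_union(polys)
        total = sum(p.area for p in polys)
        assert union.area == pytest.approx(total, rel=1e-9)
        assert len(union.interiors) == 0

    def test_mean_area_hits_target(self):
        plate = generate_hex_plate(PlateSpec(10, 10, 7.3, 1.6, 0.4, 3.0, seed=5))
        areas = [polygon_area(c) for c in plate.cells]
        assert np.mean(areas) == pytest.approx(7.3, rel=0.01)

    def test_aligned_fraction_extremes(self):
        for frac, expected in ((1.0, 1.0), (0.0, 0.0)):
            plate = generate_hex_plate(
                PlateSpec(10, 10, 2.0, 1.5, frac, 0.0, seed=1))
            summary = summarize_plate(plate)
            assert summary.aligned_fraction == pytest.approx(expected, abs=0.01)
            assert summary.mean_shape == pytest.approx(1.5, rel=0.01)


class TestGrowthSeries:
    def test_pure_expansion_conserves_counts_and_doubles_area(self):
        spec = PlateSpec(10, 8, 2.0, seed=1)
        series = generate_growth_series(
            spec, GrowthSchedule(phases=[GrowthPhase(3, area_multiplier=2.0)]))
        first, last = series.plates[0], series.plates[-1]
        assert last.n_cells == first.n_cells
        assert last.segmented_area == pytest.approx(2.0 * first.segmented_area,
                                                    rel=1e-9)

    def test_empty_schedule_is_identity(self):
        spec = PlateSpec(5, 4, 1.0, seed=9)
        series = generate_growth_series(spec, GrowthSchedule())
        assert len(series.plates) == 1
        np.testing.assert_array_equal(
            series.plates[0].cells[0].vertices,
            generate_hex_plate(spec).cells[0].vertices,
        )

    def test_elongation_schedule_increases_anisotropy(self):
        """Emulating the 36 -> 54 h window (rows +25%, columns -24%, area
        x2.2): scheduled sigma = n/m strictly increases while column count
        falls and area expands."""
        spec = PlateSpec(36, 38, 4.6, 1.3, 0.5, 2.0, seed=3)
        schedule = GrowthSchedule(
            phases=[GrowthPhase(9, 2.2, row_count_delta=9, column_count_delta=-9)],
            seed=3,
        )
        series = generate_growth_series(spec, schedule)
        sigma = series.truth["sigma"].to_numpy()
        cols = series.truth["m_per_column"].to_numpy()
        assert np.all(np.diff(sigma) > 0)
        assert cols[-1] < cols[0]
        areas = [p.segmented_area for p in series.plates]
        assert areas[-1] > 2.0 * areas[0]

    def test_schedule_driving_counts_below_one_rejected(self):
        spec = PlateSpec(4, 2, 1.0, seed=0)
        with pytest.raises(ParameterError):
            generate_growth_series(
                spec, GrowthSchedule(phases=[GrowthPhase(2, 1.0,
                                                         column_count_delta=-2)]))


class TestTrackedSeries:
    def test_single_stable_event_detected(self):
        tissue = generate_tracked_series(
            PlateSpec(8, 6, seed=4),
            T1Script(n_stable=1, n_oscillating=0, mode_deg=0.0, frames=3, seed=4),
        )
        events = [e for e in detect_t1_events(tissue) if e.stable]
        assert len(events) == 1
        assert {frozenset(e.quartet) for e in events} == \
            {frozenset(e.quartet) for e in tissue.ground_truth if e.stable}

    def test_oscillating_event_filtered(self):
        tissue = generate_tracked_series(
            PlateSpec(8, 6, seed=5),
            T1Script(n_stable=0, n_oscillating=1, frames=4, seed=5),
        )
        events = detect_t1_events(tissue)
        assert events  # the exchange is found...
        assert not [e for e in events if e.stable]  # ...but nothing is stable

    def test_static_script_changes_nothing(self):
        tissue = generate_tracked_series(
            PlateSpec(6, 5, seed=6), T1Script(n_stable=0, frames=3, seed=6))
        assert detect_t1_events(tissue) == []

    def test_too_many_events_rejected(self):
        with pytest.raises(ParameterError):
            generate_tracked_series(
                PlateSpec(3, 3, seed=0), T1Script(n_stable=50, frames=3, seed=0))


class TestAllometryGenerator:
    def test_noiseless_line_recovered_exactly(self):
        df = generate_allometry_dataset({"g": 0.51}, {"g": 2.0}, 50, 0.0, seed=0)
        fit = sma_fit(df["x"], df["y"])
        assert fit.slope == pytest.approx(0.51, rel=1e-9)
        assert fit.intercept == pytest.approx(2.0, rel=1e-9)

    def test_negative_slope_sign(self):
        df = generate_allometry_dataset({"g": -1.0}, {"g": 0.0}, 30, 0.0, seed=1)
        assert sma_fit(df["x"], df["y"]).slope == pytest.approx(-1.0, rel=1e-9)

    def test_determinism_and_schema(self):
        kwargs = dict(slopes={"a": 0.5, "b": 0.6}, intercepts={"a": 0, "b": 1},
                      n_per_group=20, noise_sd=0.05, seed=42)
        d1 = generate_allometry_dataset(**kwargs)
        d2 = generate_allometry_dataset(**kwargs)
        assert list(d1.columns) == ["group", "x", "y"]
        assert d1.equals(d2)
        assert sorted(d1["group"].unique()) == ["a", "b"]

    def test_small_group_rejected(self):
        with pytest.raises(ParameterError):
            generate_allometry_dataset({"g": 1.0}, {"g": 0.0}, 2, 0.0)


class TestRasterize:
    def test_unit_square_pixel_count(self):
        from ovimorph import CellPolygon, TissuePlate
        cell = CellPolygon(1, np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        mask = rasterize_plate(TissuePlate(cells=(cell,)), 0.1)
        assert abs(int((mask == 1).sum()) - 100) <= 25  # ~100 px, border effects

    def test_round_trip_areas_within_two_percent(self):
        from ovimorph.io import read_labeled_mask, write_labeled_mask
        plate = generate_hex_plate(PlateSpec(6, 5, 4.0, 1.4, 0.5, 2.0, seed=2))
        px = np.sqrt(4.0) / 25  # finer than sqrt(a)/20
        mask = rasterize_plate(plate, px)
        import tempfile
        with tempfile.TemporaryDirectory() as d:
            write_labeled_mask(mask, f"{d}/m.tif")
            back = read_labeled_mask(f"{d}/m.tif", px)
        assert back.n_cells == plate.n_cells
        orig = {c.cell_id: polygon_area(c) for c in plate.cells}
        for cell in back.cells:
            assert polygon_area(cell) == pytest.approx(orig[cell.cell_id], rel=0.02)

    def test_vanishing_cell_rejected(self):
        plate = generate_hex_plate(PlateSpec(3, 3, 1.0, seed=0))
        with pytest.raises(GeometryError):
            rasterize_plate(plate, 10.0)

    def test_empty_plate_all_background(self):
        from ovimorph import TissuePlate
        mask = rasterize_plate(TissuePlate(cells=()), 0.5)
        assert mask.sum() == 0


class TestRecoveryAcrossSizes:
    @pytest.mark.parametrize("n,m", [(12, 10), (20, 14)])
    def test_parameter_recovery(self, n, m):
        spec = PlateSpec(n, m, 5.0, 1.55, 0.5, 4.0, seed=n * m)
        summary = summarize_plate(generate_hex_plate(spec))
        assert summary.mean_area == pytest.approx(5.0, rel=0.02)
        assert summary.mean_shape == pytest.approx(1.55, rel=0.05)
        assert summary.anisotropy == pytest.approx(n / m, rel=0.10)
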