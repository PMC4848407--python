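"""Polygon edits, ROI counting, area statistics and export."""

import numpy as np
import pytest
import shapely.wkt
from shapely.geometry import Point, Polygon, box

from gigaslice import geometry_ops as G
from gigaslice.core_model import Ontology, Term, ValidationError
from conftest import random_simple_polygon

SQ_A = "POLYGON ((0 0, 2 0, 2 2, 0 2, 0 0))"
SQ_B = "POLYGON ((1 1, 3 1, 3 3, 1 3, 1 1))"


def ray_cast_inside(poly: Polygon, x, y, eps=1e-12):
    """Independent point-in-polygon: ray casting + boundary distance check."""
    if poly.exterior.distance(Point(x, y)) < eps:
        return True
    coords = list(poly.exterior.coords)
    inside = False
    for (x1, y1), (x2, y2) in zip(coords[:-1], coords[1:]):
        if (y1 > y) != (y2 > y):
            xin = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if xin > x:
                inside = not inside
    return inside


class TestMergeSubtract:
    def test_union_by_inclusion_exclusion(self):
        assert G.merge_polygons(SQ_A, SQ_B).area == pytest.approx(7.0)  # 4+4-1

    def test_union_idempotent(self):
        assert G.merge_polygons(SQ_A, SQ_A).area == pytest.approx(4.0)

    def test_disjoint_union_is_multipolygon(self):
        far = "POLYGON ((10 10, 11 10, 11 11, 10 11, 10 10))"
        sq = "POLYGON ((0 0, 1 0, 1 1, 0 1, 0 0))"
        out = G.merge_polygons(sq, far)
        assert out.geom_type == "MultiPolygon" and out.area == pytest.approx(2.0)

    def test_subtract_overlap(self):
        assert G.subtract_polygon(SQ_A, SQ_B).area == pytest.approx(3.0)  # 4-1

    def test_subtract_self_empty(self):
        assert G.subtract_polygon(SQ_A, SQ_A).is_empty

    def test_subtract_disjoint_identity(self):
        far = "POLYGON ((10 10, 12 10, 12 12, 10 12, 10 10))"
        assert G.subtract_polygon(SQ_A, far).equals(shapely.wkt.loads(SQ_A))

    def test_invalid_input_rejected(self):
        bowtie = "POLYGON ((0 0, 10 10, 10 0, 0 10, 0 0))"
        with pytest.raises(ValidationError):
            G.merge_polygons(bowtie, SQ_A)

    def test_inclusion_exclusion_on_random_pairs(self, rng):
        for _ in range(100):
            a = random_simple_polygon(rng, center=rng.uniform(20, 44, 2))
            b = random_simple_polygon(rng, center=rng.uniform(20, 44, 2))
            union = G.merge_polygons(a, b).area
            expected = a.area + b.area - a.intersection(b).area
            assert abs(union - expected) <= 1e-9 * max(union, 1.0)


class TestFillHoles:
    def test_hole_removed(self):
        holed = Polygon([(0, 0), (4, 0), (4, 4), (0, 4)],
                        [[(1, 1), (3, 1), (3, 3), (1, 3)]])
        assert holed.area == pytest.approx(12.0)
        assert G.fill_internal_holes(holed).area == pytest.approx(16.0)

    def test_no_holes_unchanged(self):
        sq = shapely.wkt.loads(SQ_A)
        assert G.fill_internal_holes(sq).equals(sq)

    def test_non_areal_rejected(self):
        with pytest.raises(ValidationError):
            G.fill_internal_holes("POINT (1 1)")

    def test_never_shrinks_and_idempotent(self, rng):
        for _ in range(100):
            outer = random_simple_polygon(rng, radius=(15, 30))
            hole = random_simple_polygon(rng, radius=(2, 6))
            poly = outer.difference(hole)
            if poly.geom_type != "Polygon":
                poly = max(poly.geoms, key=lambda p: p.area)
            filled = G.fill_internal_holes(poly)
            assert filled.area >= poly.area - 1e-12
            assert G.fill_internal_holes(filled).equals(filled)


class TestScale:
    def test_factor_two_quadruples_area(self):
        assert G.scale_geometry(SQ_A, 2.0).area == pytest.approx(16.0)

    def test_factor_one_identity(self):
        assert G.scale_geometry(SQ_A, 1.0).equals(shapely.wkt.loads(SQ_A))

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValidationError):
            G.scale_geometry(SQ_A, 0.0)

    def test_area_scales_by_factor_squared_and_inverts(self, rng):
        for _ in range(50):
            poly = random_simple_polygon(rng)
            f = float(rng.uniform(0.2, 4.0))
            scaled = G.scale_geometry(poly, f)
            assert scaled.area == pytest.approx(poly.area * f * f, rel=1e-9)
            back = G.scale_geometry(scaled, 1.0 / f)
            assert back.equals_exact(poly, 1e-9)


class TestEditVertex:
    def test_shoelace_area_after_corner_move(self):
        # unit square with corner (1,1) pulled to (3,3):
        # shoelace on (0,0),(1,0),(3,3),(0,1) gives 3.5
        sq = "POLYGON ((0 0, 1 0, 1 1, 0 1, 0 0))"
        edited = G.edit_vertex(sq, 0, 2, (3, 3))
        pts = [(0, 0), (1, 0), (3, 3), (0, 1)]
        shoelace = 0.5 * abs(sum(
            x1 * y2 - x2 * y1 for (x1, y1), (x2, y2)
            in zip(pts, pts[1:] + pts[:1])))
        assert edited.area == pytest.approx(shoelace)

    def test_move_to_same_position_identity(self):
        sq = shapely.wkt.loads(SQ_A)
        assert G.edit_vertex(sq, 0, 1, (2, 0)).equals(sq)

    def test_first_vertex_keeps_ring_closed(self):
        edited = G.edit_vertex(SQ_A, 0, 0, (-1, -1))
        coords = list(edited.exterior.coords)
        assert coords[0] == coords[-1] == (-1, -1)

    def test_bow_tie_creating_move_refused(self):
        sq = "POLYGON ((0 0, 4 0, 4 4, 0 4, 0 0))"
        with pytest.raises(G.InvalidEditError):
            G.edit_vertex(sq, 0, 2, (-5, 2))  # crosses the left edge

    def test_out_of_range_indices(self):
        with pytest.raises(IndexError):
            G.edit_vertex(SQ_A, 2, 0, (0, 0))
        with pytest.raises(IndexError):
            G.edit_vertex(SQ_A, 0, 7, (0, 0))


class TestCountWithin:
    def test_points_inside_and_outside(self):
        pts = ["POINT (0.5 0.5)", "POINT (1.5 1.5)", "POINT (5 5)"]
        assert G.count_within(pts, SQ_A) == 2

    def test_boundary_point_counts(self):
        assert G.count_within(["POINT (2 2)"], SQ_A) == 1

    def test_polygon_objects_count_on_overlap(self):
        assert G.count_within([SQ_B], SQ_A) == 1
        assert G.count_within(["POLYGON ((5 5, 6 5, 6 6, 5 6, 5 5))"], SQ_A) == 0

    def test_invalid_roi_rejected(self):
        with pytest.raises(ValidationError):
            G.count_within(["POINT (0 0)"],
                           "POLYGON ((0 0, 10 10, 10 0, 0 10, 0 0))")

    def test_matches_ray_casting_oracle_on_random_points(self, rng):
        roi = random_simple_polygon(rng, center=(32, 32), radius=(10, 28))
        pts = rng.uniform(0, 64, (200, 2))
        expect = sum(ray_cast_inside(roi, x, y) for x, y in pts)
        got = G.count_within([Point(x, y) for x, y in pts], roi)
        assert got == expect


class TestAreaStatistics:
    @pytest.fixture
    def ontology(self):
        return Ontology(id=1, name="o", terms=[
            Term(1, "tumor"), Term(2, "stroma")])

    def test_ratio_vs_reference(self, ontology):
        records = G.area_statistics(
            [(box(0, 0, 5, 5).wkt, 1)], ontology,
            reference_region=box(0, 0, 10, 10).wkt)
        assert records[0].ratio_vs_reference == pytest.approx(0.25)

    def test_overlapping_same_term_unioned(self, ontology):
        records = G.area_statistics(
            [(SQ_A, 1), (SQ_A, 1)], ontology)
        assert records[0].object_count == 2
        assert records[0].total_area_px2 == pytest.approx(4.0)

    def test_um2_uses_resolution_squared(self, ontology):
        records = G.area_statistics([(SQ_A, 1)], ontology, resolution=0.5)
        assert records[0].total_area_um2 == pytest.approx(4.0 * 0.25)

    def test_zero_area_reference_rejected(self, ontology):
        with pytest.raises(ValidationError):
            G.area_statistics([(SQ_A, 1)], ontology,
                              reference_region="POLYGON ((0 0, 1 0, 0 0))")

    def test_random_scene_matches_rasterization_oracle(self, ontology, rng):
        from matplotlib.path import Path
        polys = [random_simple_polygon(rng, center=rng.uniform(150, 362, 2),
                                       radius=(40, 120)) for _ in range(4)]
        records = G.area_statistics([(p.wkt, 1) for p in polys], ontology)
        # fine-grid pixel-center rasterization, independent of shapely
        step = 0.5
        xs = np.arange(step / 2, 512, step)
        pts = np.array(np.meshgrid(xs, xs)).reshape(2, -1).T
        covered = np.zeros(len(pts), dtype=bool)
        for p in polys:
            covered |= Path(np.asarray(p.exterior.coords)).contains_points(pts)
        raster_area = covered.sum() * step * step
        assert abs(records[0].total_area_px2 - raster_area) \
            <= 0.005 * raster_area


class TestExport:
    def _records(self):
        return [G.QuantificationRecord(1, "tumor", 3, 25.0, 6.25, 0.25),
                G.QuantificationRecord(2, "stroma", 1, 10.0, None, None)]

    def test_empty_records_header_only_csv(self, tmp_path):
        path = tmp_path / "stats.csv"
        G.export_statistics([], path)
        assert path.read_text().strip() == \
            "term_id,term_name,object_count,area_px2,area_um2,ratio"

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "stats.csv"
        G.export_statistics(self._records(), path, "csv")
        assert G.import_statistics(path, "csv") == self._records()

    def test_json_round_trip(self, tmp_path):
        path = tmp_path / "stats.json"
        G.export_statistics(self._records(), path, "json")
        assert G.import_statistics(path, "json") == self._records()

    def test_field_order(self, tmp_path):
        path = tmp_path / "stats.csv"
        G.export_statistics(self._records()[:1], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2
        assert lines[1].startswith("1,tumor,3,25.0")
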