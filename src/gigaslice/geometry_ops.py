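"""Polygon editing and spatial quantification.

The proofreading edits experts apply to annotations (merge, subtract,
scale, vertex moves, hole filling) are expressed as spatial operations on
WKT polygons, and the downstream quantification questions — per-term areas,
tumor-to-tissue ratios, spot counts inside regions of interest — as
spatial queries.  All geometry goes through shapely; WKT strings are the
exchange currency at module boundaries.

Conventions (documented choices):

* counting uses a *closed* boundary rule — an object touching the ROI
  boundary counts;
* same-term annotations are unioned before measuring area, so a region
  drawn twice is not counted twice and ratios stay <= 1;
* edits producing invalid geometry are refused, never auto-repaired.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict

import shapely
import shapely.affinity
import shapely.wkt
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .core_model import ValidationError


class InvalidEditError(ValueError):
    """A manual edit would produce invalid geometry and is refused."""


def _as_geom(g) -> BaseGeometry:
    geom = shapely.wkt.loads(g) if isinstance(g, str) else g
    if not geom.is_valid:
        raise ValidationError(f"invalid geometry: {shapely.is_valid_reason(geom)}")
    return geom


def _as_areal(g) -> BaseGeometry:
    geom = _as_geom(g)
    if geom.geom_type not in ("Polygon", "MultiPolygon"):
        raise ValidationError(f"expected areal geometry, got {geom.geom_type}")
    return geom


# ---------------------------------------------------------------------------
# Editing operations
# ---------------------------------------------------------------------------

def merge_polygons(a, b) -> BaseGeometry:
    """Geometric union of two polygons (annotation 'merge' edit)."""
    return unary_union([_as_areal(a), _as_areal(b)])


def subtract_polygon(a, b) -> BaseGeometry:
    """Remove *b* from *a*; the result may be empty."""
    return _as_areal(a).difference(_as_areal(b))


def fill_internal_holes(p) -> BaseGeometry:
    """Drop every interior ring, keeping exterior rings unchanged."""
    geom = _as_areal(p)
    if geom.geom_type == "Polygon":
        return Polygon(geom.exterior)
    return MultiPolygon([Polygon(part.exterior) for part in geom.geoms])


def scale_geometry(g, factor: float, origin="centroid") -> BaseGeometry:
    """Similarity scaling about the centroid or an explicit (x, y) point."""
    if factor <= 0:
        raise ValidationError("scale factor must be > 0")
    geom = _as_geom(g)
    if origin == "centroid":
        origin = geom.centroid
    return shapely.affinity.scale(geom, xfact=factor, yfact=factor, origin=origin)


def edit_vertex(p, ring: int, vertex: int, new_xy) -> BaseGeometry:
    """Move one vertex of a polygon ring; refuse edits that break validity.

    ``ring`` 0 is the exterior, 1.. index the interior rings.  Moving the
    first vertex keeps the closing vertex synchronized.
    """
    geom = _as_areal(p)
    if geom.geom_type != "Polygon":
        raise ValidationError("edit_vertex operates on single polygons")
    rings = [list(geom.exterior.coords)] + [list(r.coords) for r in geom.interiors]
    if not (0 <= ring < len(rings)):
        raise IndexError(f"ring {ring} out of range")
    coords = rings[ring]
    n = len(coords) - 1  # closing vertex duplicates the first
    if not (0 <= vertex < n):
        raise IndexError(f"vertex {vertex} out of range")
    coords[vertex] = tuple(new_xy)
    if vertex == 0:
        coords[-1] = tuple(new_xy)
    edited = Polygon(rings[0], rings[1:])
    if not edited.is_valid or edited.area == 0:
        raise InvalidEditError(
            f"edit refused: {shapely.is_valid_reason(edited)}")
    return edited


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

def count_within(objects, roi) -> int:
    """Count objects whose geometry intersects the closed ROI.

    Points on the ROI boundary count; polygons count on any non-empty
    intersection.  ``objects`` may be WKT strings, shapely geometries or
    annotations exposing ``.shape()``.
    """
    roi_geom = _as_areal(roi)
    n = 0
    for obj in objects:
        geom = obj.shape() if hasattr(obj, "shape") else _as_geom(obj)
        if roi_geom.intersects(geom):
            n += 1
    return n


@dataclass
class QuantificationRecord:
    term_id: int
    term_name: str
    object_count: int
    total_area_px2: float
    total_area_um2: float | None = None
    ratio_vs_reference: float | None = None


def area_statistics(annotations, ontology, reference_region=None,
                    resolution=None) -> list:
    """Per-term object counts, union areas and optional reference ratios.

    Overlapping annotations sharing a term are unioned before measuring so
    double-drawn regions are not double-counted.  ``ratio_vs_reference`` is
    area(term union ∩ reference) / area(reference).  Physical areas use
    ``resolution`` in µm/px.  Records are sorted by term id; terms without
    annotations are omitted.
    """
    ref = None
    if reference_region is not None:
        ref = _as_areal(reference_region)
        if ref.area == 0:
            raise ValidationError("reference region has zero area")
    by_term: dict[int, list] = {}
    counts: dict[int, int] = {}
    for ann in annotations:
        geom = ann.shape() if hasattr(ann, "shape") else _as_geom(ann[0])
        term_ids = ann.term_ids if hasattr(ann, "term_ids") else {ann[1]}
        for tid in term_ids:
            by_term.setdefault(tid, []).append(geom)
            counts[tid] = counts.get(tid, 0) + 1
    records = []
    for tid in sorted(by_term):
        union = unary_union(by_term[tid])
        area_px2 = union.area
        rec = QuantificationRecord(
            term_id=tid,
            term_name=ontology.term(tid).name,
            object_count=counts[tid],
            total_area_px2=area_px2,
            total_area_um2=(area_px2 * resolution ** 2
                            if resolution is not None else None),
            ratio_vs_reference=(union.intersection(ref).area / ref.area
                                if ref is not None else None),
        )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Statistics export / import
# ---------------------------------------------------------------------------

CSV_FIELDS = ("term_id", "term_name", "object_count", "area_px2", "area_um2", "ratio")


def export_statistics(records, path, format="csv") -> None:
    """Write quantification records to CSV or JSON; re-import round-trips."""
    rows = [{
        "term_id": r.term_id,
        "term_name": r.term_name,
        "object_count": r.object_count,
        "area_px2": r.total_area_px2,
        "area_um2": r.total_area_um2,
        "ratio": r.ratio_vs_reference,
    } for r in records]
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_FIELDS)
            writer.writeheader()
            for row in rows:
                writer.writerow({k: ("" if v is None else v) for k, v in row.items()})
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")


def import_statistics(path, format="csv") -> list:
    """Read quantification records written by :func:`export_statistics`."""
    if format == "csv":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        rows = [{k: (None if v == "" else v) for k, v in row.items()} for row in rows]
    elif format == "json":
        with open(path) as fh:
            rows = json.load(fh)
    else:
        raise ValueError(f"unknown format {format!r}")
    return [QuantificationRecord(
        term_id=int(r["term_id"]),
        term_name=r["term_name"],
        object_count=int(r["object_count"]),
        total_area_px2=float(r["area_px2"]),
        total_area_um2=None if r["area_um2"] is None else float(r["area_um2"]),
        ratio_vs_reference=None if r["ratio"] is None else float(r["ratio"]),
    ) for r in rows]
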