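"""Project / ontology / image / annotation entity model.

Entities mirror the data model of a collaborative annotation platform: a
project owns an ontology (a forest of semantic terms), images live in
projects, annotations are WKT geometries on an image plane inside a named
layer and carry ontology terms plus free key-value metadata.  An
:class:`EntityStore` provides in-memory persistence with referential
integrity and monotonically increasing integer ids.

Coordinate convention: 0-based pixel coordinates, origin at the top-left,
y increasing downward, half-open extents ``[0, width) x [0, height)``.
Viewers that place the origin at the bottom-left can convert with
:func:`flip_y`.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields

import shapely
import shapely.wkt
from shapely.geometry import mapping as geo_mapping, shape as geo_shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

logger = logging.getLogger("gigaslice")

AGENT_KINDS = ("human", "software", "review")


class ValidationError(ValueError):
    """An entity violates one of its invariants."""


class SerializationError(ValueError):
    """An entity (or JSON document) cannot be (de)serialized."""


class StoreError(KeyError):
    """A referenced entity does not exist in the store."""


class BlindedModeError(ValueError):
    """Blinded projection requested on a project without the blinded flag."""


# ---------------------------------------------------------------------------
# Entities
# ---------------------------------------------------------------------------

@dataclass
class Project:
    id: int
    name: str
    ontology_id: int
    blinded: bool = False
    properties: dict = field(default_factory=dict)


@dataclass
class Term:
    id: int
    name: str
    color: tuple = (255, 0, 0)
    parent_id: int | None = None

    def validate(self) -> None:
        if not self.name:
            raise ValidationError("Term name must be non-empty")
        if len(tuple(self.color)) != 3 or any(
            not (0 <= int(c) <= 255) for c in self.color
        ):
            raise ValidationError(f"Term color {self.color!r} not an RGB triple in [0,255]")


@dataclass
class Ontology:
    id: int
    name: str
    terms: list = field(default_factory=list)

    def validate(self) -> None:
        ids = [t.id for t in self.terms]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate term ids in ontology")
        known = set(ids)
        for t in self.terms:
            t.validate()
            if t.parent_id is not None and t.parent_id not in known:
                raise ValidationError(f"term {t.id} has unknown parent {t.parent_id}")
        # parent references must form a forest (no cycles)
        for t in self.terms:
            seen = set()
            cur = t
            by_id = {u.id: u for u in self.terms}
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise ValidationError("cycle in term parent references")
                seen.add(cur.id)
                cur = by_id[cur.parent_id]

    def term(self, term_id: int) -> Term:
        for t in self.terms:
            if t.id == term_id:
                return t
        raise StoreError(f"unknown term {term_id}")

    @property
    def term_ids(self) -> set:
        return {t.id for t in self.terms}


@dataclass
class ImageInstance:
    id: int
    project_id: int
    name: str
    width: int
    height: int
    n_channels: int = 1
    n_zslices: int = 1
    n_timepoints: int = 1
    resolution: float | None = None  # µm per pixel
    source_path: str = ""
    properties: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValidationError("image dimensions must be >= 1")
        if min(self.n_channels, self.n_zslices, self.n_timepoints) < 1:
            raise ValidationError("plane counts must be >= 1")
        if self.resolution is not None and self.resolution <= 0:
            raise ValidationError("resolution must be > 0 when present")


@dataclass
class AnnotationLayer:
    id: int
    image_id: int
    agent_id: int
    agent_kind: str = "human"

    def validate(self) -> None:
        if self.agent_kind not in AGENT_KINDS:
            raise ValidationError(f"agent_kind must be one of {AGENT_KINDS}")


@dataclass
class Annotation:
    id: int
    image_id: int
    layer_id: int
    geometry: str  # WKT: Point, Polygon or MultiPolygon
    plane: tuple = (0, 0, 0)  # (z, c, t)
    term_ids: set = field(default_factory=set)
    properties: dict = field(default_factory=dict)
    description: str | None = None

    def shape(self) -> BaseGeometry:
        return shapely.wkt.loads(self.geometry)


ENTITY_TYPES = {
    "Project": Project,
    "Ontology": Ontology,
    "Term": Term,
    "ImageInstance": ImageInstance,
    "AnnotationLayer": AnnotationLayer,
    "Annotation": Annotation,
}


def flip_y(wkt: str, height: int) -> str:
    """Convert a geometry between top-left- and bottom-left-origin frames."""
    geom = shapely.wkt.loads(wkt)
    return shapely.ops.transform(lambda x, y: (x, height - y), geom).wkt


# ---------------------------------------------------------------------------
# Geometry validation / repair
# ---------------------------------------------------------------------------

def clean_geometry(wkt: str) -> BaseGeometry:
    """Parse WKT and repair invalid polygons by zero-buffer cleaning.

    Degenerate output (empty, or zero-area where a polygon was supplied)
    raises :class:`ValidationError`.  Repairs are logged.
    """
    try:
        geom = shapely.wkt.loads(wkt)
    except Exception as exc:  # shapely raises GEOSException subclasses
        raise ValidationError(f"invalid WKT: {exc}") from exc
    if geom.geom_type not in ("Point", "Polygon", "MultiPolygon"):
        raise ValidationError(f"unsupported geometry type {geom.geom_type}")
    if not geom.is_valid:
        repaired = geom.buffer(0)
        if repaired.is_empty or not repaired.is_valid:
            repaired = make_valid(geom)
        logger.warning("repaired invalid geometry at ingestion: %s", wkt[:60])
        geom = repaired
    if geom.is_empty or (geom.geom_type != "Point" and geom.area == 0):
        raise ValidationError("degenerate geometry (empty or zero-area polygon)")
    return geom


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def _to_jsonable(value):
    if isinstance(value, (set, frozenset)):
        return sorted(value)
    if isinstance(value, tuple):
        return list(value)
    if isinstance(value, dict):
        return {str(k): _to_jsonable(v) for k, v in value.items()}
    if isinstance(value, list):
        return [_to_jsonable(v) for v in value]
    if isinstance(value, Term):
        return dict(serialize_fields(value), type="Term")
    if value is None or isinstance(value, (str, int, float, bool)):
        return value
    raise SerializationError(f"unserializable value of type {type(value).__name__}")


def serialize_fields(entity) -> dict:
    out = {}
    for f in dc_fields(entity):
        try:
            out[f.name] = _to_jsonable(getattr(entity, f.name))
        except SerializationError as exc:
            raise SerializationError(f"field {f.name!r}: {exc}") from exc
    return out


def serialize_entity(entity) -> str:
    """Serialize any entity to a JSON document carrying a ``type`` field."""
    type_name = type(entity).__name__
    if type_name not in ENTITY_TYPES:
        raise SerializationError(f"unknown entity type {type_name}")
    doc = serialize_fields(entity)
    doc["type"] = type_name
    return json.dumps(doc, sort_keys=True)


def parse_entity(text: str):
    """Parse a JSON document into an entity; ``parse(serialize(e)) == e``."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SerializationError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "type" not in doc:
        raise SerializationError("JSON document lacks a 'type' discriminator")
    type_name = doc.pop("type")
    if type_name not in ENTITY_TYPES:
        raise SerializationError(f"unknown entity type {type_name!r}")
    cls = ENTITY_TYPES[type_name]
    known = {f.name for f in dc_fields(cls)}
    unknown = set(doc) - known
    if unknown:
        raise SerializationError(f"unknown fields for {type_name}: {sorted(unknown)}")
    kwargs = dict(doc)
    if type_name == "Term":
        kwargs["color"] = tuple(kwargs.get("color", (255, 0, 0)))
    if type_name == "Ontology":
        kwargs["terms"] = [
            parse_entity(json.dumps(t)) if isinstance(t, dict) else t
            for t in kwargs.get("terms", [])
        ]
    if issubclass(cls, Annotation):
        kwargs["term_ids"] = set(kwargs.get("term_ids", []))
        kwargs["plane"] = tuple(kwargs.get("plane", (0, 0, 0)))
        clean_geometry(kwargs["geometry"])  # validity check
    entity = cls(**kwargs)
    if hasattr(entity, "validate"):
        entity.validate()
    return entity


# ---------------------------------------------------------------------------
# Store
# ---------------------------------------------------------------------------

class EntityStore:
    """In-memory entity store with referential integrity.

    Ids are monotonically increasing integers assigned by the store when an
    entity is added with ``id=None``; ids are never reused.
    """

    def __init__(self) -> None:
        self.projects: dict[int, Project] = {}
        self.ontologies: dict[int, Ontology] = {}
        self.images: dict[int, ImageInstance] = {}
        self.layers: dict[int, AnnotationLayer] = {}
        self.annotations: dict[int, Annotation] = {}
        self._next_id = 1

    def next_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def _claim(self, entity, collection) -> None:
        if entity.id is None:
            entity.id = self.next_id()
        elif entity.id in collection:
            raise StoreError(f"id {entity.id} already in use")
        else:
            self._next_id = max(self._next_id, entity.id + 1)
        collection[entity.id] = entity

    # -- insertion ---------------------------------------------------------
    def add_ontology(self, ontology: Ontology) -> Ontology:
        ontology.validate()
        self._claim(ontology, self.ontologies)
        return ontology

    def add_project(self, project: Project) -> Project:
        if project.ontology_id not in self.ontologies:
            raise StoreError(f"unknown ontology {project.ontology_id}")
        self._claim(project, self.projects)
        return project

    def add_image(self, image: ImageInstance) -> ImageInstance:
        image.validate()
        if image.project_id not in self.projects:
            raise StoreError(f"unknown project {image.project_id}")
        self._claim(image, self.images)
        return image

    def add_layer(self, layer: AnnotationLayer) -> AnnotationLayer:
        layer.validate()
        if layer.image_id not in self.images:
            raise StoreError(f"unknown image {layer.image_id}")
        key = (layer.image_id, layer.agent_id, layer.agent_kind)
        for other in self.layers.values():
            if (other.image_id, other.agent_id, other.agent_kind) == key:
                raise ValidationError(f"duplicate layer {key}")
        self._claim(layer, self.layers)
        return layer

    def add_annotation(self, ann: Annotation) -> Annotation:
        if ann.image_id not in self.images:
            raise StoreError(f"unknown image {ann.image_id}")
        if ann.layer_id not in self.layers:
            raise StoreError(f"unknown layer {ann.layer_id}")
        image = self.images[ann.image_id]
        geom = clean_geometry(ann.geometry)
        ann.geometry = geom.wkt  # store repaired form
        minx, miny, maxx, maxy = geom.bounds
        if minx < 0 or miny < 0 or maxx > image.width or maxy > image.height:
            raise ValidationError(
                f"geometry bounds {geom.bounds} exceed image extent "
                f"{image.width}x{image.height}"
            )
        ontology = self.ontologies[self.projects[image.project_id].ontology_id]
        unknown = set(ann.term_ids) - ontology.term_ids
        if unknown:
            raise ValidationError(f"unknown term ids {sorted(unknown)}")
        z, c, t = ann.plane
        if not (0 <= z < image.n_zslices and 0 <= c < image.n_channels
                and 0 <= t < image.n_timepoints):
            raise ValidationError(f"plane {ann.plane} outside image plane counts")
        self._claim(ann, self.annotations)
        return ann

    # -- lookup ------------------------------------------------------------
    def ontology_of_image(self, image_id: int) -> Ontology:
        image = self.images[image_id]
        return self.ontologies[self.projects[image.project_id].ontology_id]

    def annotations_in_layer(self, layer_id: int) -> list:
        return sorted(
            (a for a in self.annotations.values() if a.layer_id == layer_id),
            key=lambda a: a.id,
        )


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def filter_annotations(store: EntityStore, image_id=None, layer_ids=None,
                       term_ids=None, bbox=None, agent_kind=None) -> list:
    """Return annotations matching *all* provided criteria, sorted by id.

    ``term_ids`` matches on non-empty intersection; ``bbox`` (xmin, ymin,
    xmax, ymax, pixel coordinates of the image) on bounding-box overlap.
    """
    if image_id is not None and image_id not in store.images:
        raise StoreError(f"unknown image {image_id}")
    out = []
    for ann in store.annotations.values():
        if image_id is not None and ann.image_id != image_id:
            continue
        if layer_ids is not None and ann.layer_id not in set(layer_ids):
            continue
        if term_ids is not None and not (set(term_ids) & ann.term_ids):
            continue
        if agent_kind is not None:
            if store.layers[ann.layer_id].agent_kind != agent_kind:
                continue
        if bbox is not None:
            minx, miny, maxx, maxy = ann.shape().bounds
            qx0, qy0, qx1, qy1 = bbox
            if maxx < qx0 or minx > qx1 or maxy < qy0 or miny > qy1:
                continue
        out.append(ann)
    return sorted(out, key=lambda a: a.id)


def observer_ordinals(store: EntityStore, project: Project) -> dict:
    """Stable agent_id -> ordinal map over the project's annotation layers.

    Ordinals follow sorted agent id, so they do not depend on insertion
    order.
    """
    image_ids = {i.id for i in store.images.values() if i.project_id == project.id}
    agents = sorted({l.agent_id for l in store.layers.values()
                     if l.image_id in image_ids})
    return {a: k + 1 for k, a in enumerate(agents)}


def apply_blinded_view(store: EntityStore, project: Project, entity):
    """Return a redacted copy of *entity* for blinded assessment.

    Image names/paths become ``image-<id>``; layer agents become
    ``observer-<ordinal>``.  Geometry, terms and quantification-relevant
    fields are never altered.
    """
    if not project.blinded:
        raise BlindedModeError("project is not in blinded mode")
    out = copy.deepcopy(entity)
    if isinstance(out, ImageInstance):
        out.name = f"image-{out.id}"
        out.source_path = f"image-{out.id}"
    elif isinstance(out, AnnotationLayer):
        ordinals = observer_ordinals(store, project)
        out.agent_id = f"observer-{ordinals[entity.agent_id]}"
    return out


def attach_property(store: EntityStore, entity_ref, key: str, value: str) -> EntityStore:
    """Attach (or overwrite) a key-value property on a project, image or
    annotation.  ``entity_ref`` is ``(kind, id)`` with kind in
    {"project", "image", "annotation"}."""
    if not key:
        raise ValidationError("property key must be non-empty")
    kind, eid = entity_ref
    collection = {"project": store.projects, "image": store.images,
                  "annotation": store.annotations}.get(kind)
    if collection is None or eid not in collection:
        raise StoreError(f"unknown entity {entity_ref}")
    collection[eid].properties[key] = value
    return store


# ---------------------------------------------------------------------------
# Store persistence (JSON document array)
# ---------------------------------------------------------------------------

def save_store(store: EntityStore, path) -> None:
    """Write every entity as one JSON array, in dependency order."""
    docs = []
    for collection in (store.ontologies, store.projects, store.images,
                       store.layers, store.annotations):
        for entity in sorted(collection.values(), key=lambda e: e.id):
            docs.append(json.loads(serialize_entity(entity)))
    with open(path, "w") as fh:
        json.dump(docs, fh, indent=1)


def load_store(path) -> EntityStore:
    with open(path) as fh:
        docs = json.load(fh)
    store = EntityStore()
    adders = {"Ontology": store.add_ontology, "Project": store.add_project,
              "ImageInstance": store.add_image,
              "AnnotationLayer": store.add_layer}
    for doc in docs:
        entity = parse_entity(json.dumps(doc))
        adders.get(doc["type"], store.add_annotation)(entity)
    return store


# ---------------------------------------------------------------------------
# GeoJSON interchange
# ---------------------------------------------------------------------------

def annotations_to_geojson(store: EntityStore, annotations) -> dict:
    """Export annotations as a GeoJSON FeatureCollection."""
    features = []
    for ann in annotations:
        ontology = store.ontology_of_image(ann.image_id)
        layer = store.layers[ann.layer_id]
        features.append({
            "type": "Feature",
            "geometry": geo_mapping(ann.shape()),
            "properties": {
                "annotation_id": ann.id,
                "layer": layer.id,
                "terms": sorted(ontology.term(t).name for t in ann.term_ids),
                "plane": {"z": ann.plane[0], "c": ann.plane[1], "t": ann.plane[2]},
            },
        })
    return {"type": "FeatureCollection", "features": features}


def annotations_from_geojson(store: EntityStore, doc: dict, image_id: int,
                             layer_id: int) -> list:
    """Import a FeatureCollection as annotations on one image layer.

    Term names in each feature's ``terms`` property are resolved against
    the project ontology.
    """
    if doc.get("type") != "FeatureCollection":
        raise ValidationError("expected a GeoJSON FeatureCollection")
    ontology = store.ontology_of_image(image_id)
    name_to_id = {t.name: t.id for t in ontology.terms}
    created = []
    for feat in doc.get("features", []):
        geom = geo_shape(feat["geometry"])
        props = feat.get("properties", {})
        plane = props.get("plane", {})
        terms = set()
        for name in props.get("terms", []):
            if name not in name_to_id:
                raise ValidationError(f"unknown term name {name!r}")
            terms.add(name_to_id[name])
        ann = Annotation(
            id=None, image_id=image_id, layer_id=layer_id, geometry=geom.wkt,
            plane=(plane.get("z", 0), plane.get("c", 0), plane.get("t", 0)),
            term_ids=terms,
        )
        created.append(store.add_annotation(ann))
    return created
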