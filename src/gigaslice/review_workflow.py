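"""Proofreading of human- or machine-generated annotations.

Experts accept, reject or edit annotations from source layers into a
distinct *review* layer.  Reviewed annotations are novel entities — copies
carrying a provenance link and an action tag — and originals are never
modified, so quantification on the reviewed layer can be audited against
the raw layers.  One review layer exists per image; decisions are explicit,
revocable before finalization and frozen afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_model import (Annotation, AnnotationLayer, EntityStore, StoreError,
                         ValidationError, clean_geometry)
from . import geometry_ops

REVIEW_AGENT = 0  # shared agent id of the per-image review layer


class ReviewError(ValueError):
    """Illegal review action (double decision, finalized session, ...)."""


@dataclass
class ReviewedAnnotation(Annotation):
    original_id: int | None = None
    action: str = "accepted"     # accepted | edited | added
    reviewer_id: int | None = None


# reviewed annotations are first-class entities in JSON documents
from .core_model import ENTITY_TYPES as _ENTITY_TYPES  # noqa: E402
_ENTITY_TYPES["ReviewedAnnotation"] = ReviewedAnnotation


@dataclass
class ReviewSession:
    id: int
    image_id: int
    reviewer_id: int
    source_layer_ids: set
    review_layer_id: int
    state: str = "open"          # open | finalized
    decisions: dict = field(default_factory=dict)

    def _require_open(self):
        if self.state != "open":
            raise ReviewError("session is finalized")

    def _require_undecided(self, annotation_id):
        if annotation_id in self.decisions:
            raise ReviewError(
                f"annotation {annotation_id} already decided "
                f"({self.decisions[annotation_id]}); revoke first")


def _review_layer(store: EntityStore, image_id: int) -> AnnotationLayer:
    for layer in store.layers.values():
        if layer.image_id == image_id and layer.agent_kind == "review":
            return layer
    return store.add_layer(AnnotationLayer(
        id=None, image_id=image_id, agent_id=REVIEW_AGENT, agent_kind="review"))


def start_review(store: EntityStore, image_id: int, reviewer_id: int,
                 source_layer_ids) -> ReviewSession:
    """Open a proofreading session over existing layers of one image.

    The image's review layer is created on first use and reused afterwards.
    """
    if image_id not in store.images:
        raise StoreError(f"unknown image {image_id}")
    source_layer_ids = set(source_layer_ids)
    for lid in source_layer_ids:
        if lid not in store.layers or store.layers[lid].image_id != image_id:
            raise StoreError(f"layer {lid} does not exist on image {image_id}")
    review_layer = _review_layer(store, image_id)
    return ReviewSession(id=store.next_id(), image_id=image_id,
                         reviewer_id=reviewer_id,
                         source_layer_ids=source_layer_ids,
                         review_layer_id=review_layer.id)


def _source_annotation(store, session, annotation_id) -> Annotation:
    ann = store.annotations.get(annotation_id)
    if ann is None or ann.layer_id not in session.source_layer_ids:
        raise StoreError(f"annotation {annotation_id} not in a source layer")
    return ann


def _insert_reviewed(store, session, geometry, term_ids, action,
                     original_id=None, plane=(0, 0, 0)) -> ReviewedAnnotation:
    rev = ReviewedAnnotation(
        id=None, image_id=session.image_id, layer_id=session.review_layer_id,
        geometry=geometry, plane=plane, term_ids=set(term_ids),
        original_id=original_id, action=action, reviewer_id=session.reviewer_id)
    store.add_annotation(rev)
    return rev


def accept_annotation(store: EntityStore, session: ReviewSession,
                      annotation_id: int) -> ReviewedAnnotation:
    """Copy an annotation verbatim into the review layer (action=accepted)."""
    session._require_open()
    session._require_undecided(annotation_id)
    ann = _source_annotation(store, session, annotation_id)
    rev = _insert_reviewed(store, session, ann.geometry, ann.term_ids,
                           "accepted", original_id=ann.id, plane=ann.plane)
    session.decisions[annotation_id] = "accepted"
    return rev


def reject_annotation(store: EntityStore, session: ReviewSession,
                      annotation_id: int) -> ReviewSession:
    """Record a rejection; nothing enters the review layer."""
    session._require_open()
    session._require_undecided(annotation_id)
    _source_annotation(store, session, annotation_id)
    session.decisions[annotation_id] = "rejected"
    return session


def edit_and_accept(store: EntityStore, session: ReviewSession,
                    annotation_id: int, new_geometry=None,
                    new_terms=None) -> ReviewedAnnotation:
    """Reviewed copy with corrected geometry and/or terms (action=edited)."""
    session._require_open()
    session._require_undecided(annotation_id)
    if new_geometry is None and new_terms is None:
        raise ReviewError("provide new geometry and/or new terms")
    ann = _source_annotation(store, session, annotation_id)
    geometry = ann.geometry
    if new_geometry is not None:
        geom = clean_geometry(new_geometry) if isinstance(new_geometry, str) \
            else new_geometry
        if not geom.is_valid:
            raise ValidationError("edited geometry is invalid")
        geometry = geom.wkt
    terms = set(new_terms) if new_terms is not None else ann.term_ids
    rev = _insert_reviewed(store, session, geometry, terms, "edited",
                           original_id=ann.id, plane=ann.plane)
    session.decisions[annotation_id] = "edited"
    return rev


def add_reviewed_annotation(store: EntityStore, session: ReviewSession,
                            geometry, term_ids) -> ReviewedAnnotation:
    """Reviewer-drawn annotation directly in the review layer (action=added)."""
    session._require_open()
    return _insert_reviewed(store, session, geometry, term_ids, "added")


def revoke_decision(session: ReviewSession, annotation_id: int,
                    store: EntityStore) -> None:
    """Undo a decision before finalization (removes any reviewed copy)."""
    session._require_open()
    if annotation_id not in session.decisions:
        raise ReviewError(f"no decision on annotation {annotation_id}")
    del session.decisions[annotation_id]
    for rid, ann in list(store.annotations.items()):
        if (isinstance(ann, ReviewedAnnotation)
                and ann.layer_id == session.review_layer_id
                and ann.original_id == annotation_id):
            del store.annotations[rid]


def finalize_review(store: EntityStore, session: ReviewSession,
                    stats_path=None, stats_format="csv") -> list:
    """Freeze the session and quantify the reviewed layer.

    Returns the per-term quantification records (optionally exported);
    further decisions on the session are refused.
    """
    session._require_open()
    session.state = "finalized"
    reviewed = store.annotations_in_layer(session.review_layer_id)
    ontology = store.ontology_of_image(session.image_id)
    resolution = store.images[session.image_id].resolution
    records = geometry_ops.area_statistics(reviewed, ontology,
                                           resolution=resolution)
    if stats_path is not None:
        geometry_ops.export_statistics(records, stats_path, stats_format)
    return records


def reviewed_layer_geojson(store: EntityStore, session: ReviewSession) -> dict:
    """Reviewed layer as GeoJSON with action / provenance properties."""
    import shapely.wkt
    from shapely.geometry import mapping
    features = []
    for ann in store.annotations_in_layer(session.review_layer_id):
        features.append({
            "type": "Feature",
            "geometry": mapping(shapely.wkt.loads(ann.geometry)),
            "properties": {"annotation_id": ann.id,
                           "action": ann.action,
                           "original_id": ann.original_id,
                           "reviewer": ann.reviewer_id},
        })
    return {"type": "FeatureCollection", "features": features}
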