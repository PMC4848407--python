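"""Shared fixtures: small stores, random entity generators, random polygons."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from gigaslice import core_model as cm


def random_simple_polygon(rng, center=(32, 32), radius=(8, 24), n_vertices=None):
    """Random star-convex polygon (always simple and valid)."""
    n = int(n_vertices or rng.integers(4, 12))
    gaps = rng.uniform(0.05, 1.0, n)  # bounded-away gaps keep angles distinct
    angles = 2 * np.pi * np.cumsum(gaps) / gaps.sum()
    radii = rng.uniform(*radius, n)
    cx, cy = center
    pts = np.column_stack([cx + radii * np.cos(angles),
                           cy + radii * np.sin(angles)])
    poly = Polygon(pts)
    assert poly.is_valid and poly.area > 0
    return poly


def random_term(rng, tid):
    return cm.Term(id=tid, name=f"term-{tid}",
                   color=tuple(int(c) for c in rng.integers(0, 256, 3)))


def random_entity(rng, kind):
    if kind == "Term":
        return random_term(rng, int(rng.integers(1, 1000)))
    if kind == "Ontology":
        return cm.Ontology(id=int(rng.integers(1, 1000)), name="onto",
                           terms=[random_term(rng, i + 1)
                                  for i in range(rng.integers(1, 5))])
    if kind == "Project":
        return cm.Project(id=int(rng.integers(1, 1000)), name="proj",
                          ontology_id=1, blinded=bool(rng.integers(2)),
                          properties={"stain": "H&E"})
    if kind == "ImageInstance":
        return cm.ImageInstance(
            id=int(rng.integers(1, 1000)), project_id=1, name="img.tif",
            width=int(rng.integers(1, 5000)), height=int(rng.integers(1, 5000)),
            n_channels=int(rng.integers(1, 4)), n_zslices=int(rng.integers(1, 4)),
            n_timepoints=int(rng.integers(1, 4)),
            resolution=float(rng.uniform(0.1, 2.0)), source_path="/data/img.tif")
    if kind == "AnnotationLayer":
        return cm.AnnotationLayer(id=int(rng.integers(1, 1000)), image_id=1,
                                  agent_id=int(rng.integers(1, 50)),
                                  agent_kind=["human", "software", "review"][
                                      rng.integers(3)])
    if kind == "Annotation":
        poly = random_simple_polygon(rng)
        return cm.Annotation(
            id=int(rng.integers(1, 1000)), image_id=1, layer_id=1,
            geometry=poly.wkt, plane=(0, 0, 0),
            term_ids={int(t) for t in rng.integers(1, 10, rng.integers(1, 4))},
            properties={"origin": "test"}, description=None)
    raise ValueError(kind)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_store():
    """One project, one 512x512 image, two layers, three annotations."""
    store = cm.EntityStore()
    ont = store.add_ontology(cm.Ontology(id=None, name="onto", terms=[
        cm.Term(1, "tumor", (255, 0, 0)), cm.Term(2, "stroma", (0, 255, 0)),
        cm.Term(3, "necrosis", (0, 0, 255))]))
    proj = store.add_project(cm.Project(id=None, name="demo",
                                        ontology_id=ont.id, blinded=True))
    image = store.add_image(cm.ImageInstance(
        id=None, project_id=proj.id, name="patient_007.tif", width=512,
        height=512, resolution=0.5, source_path="/slides/patient_007.tif"))
    human = store.add_layer(cm.AnnotationLayer(id=None, image_id=image.id,
                                               agent_id=11, agent_kind="human"))
    soft = store.add_layer(cm.AnnotationLayer(id=None, image_id=image.id,
                                              agent_id=7, agent_kind="software"))
    store.add_annotation(cm.Annotation(
        id=None, image_id=image.id, layer_id=human.id,
        geometry="POLYGON ((10 10, 110 10, 110 110, 10 110, 10 10))",
        term_ids={1}))
    store.add_annotation(cm.Annotation(
        id=None, image_id=image.id, layer_id=human.id,
        geometry="POINT (250 250)", term_ids={2}))
    store.add_annotation(cm.Annotation(
        id=None, image_id=image.id, layer_id=soft.id,
        geometry="POLYGON ((300 300, 400 300, 400 400, 300 400, 300 300))",
        term_ids={1, 3}))
    return store
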