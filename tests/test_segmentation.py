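"""Multi-output pixel classification: sampling, training, prediction."""

import numpy as np
import pytest

from gigaslice import core_model as cm
from gigaslice import fixtures, segmentation as S
from gigaslice.core_model import ValidationError


def two_texture_store(scene, n_terms=2):
    """Store holding the scene's truth islets (term 1) + background boxes."""
    store = cm.EntityStore()
    terms = [cm.Term(1, "islet"), cm.Term(2, "background")][:n_terms]
    ont = store.add_ontology(cm.Ontology(id=None, name="o", terms=terms))
    proj = store.add_project(cm.Project(id=None, name="p", ontology_id=ont.id))
    h, w = scene.image.shape[:2]
    img = store.add_image(cm.ImageInstance(id=None, project_id=proj.id,
                                           name="syn", width=w, height=h))
    layer = store.add_layer(cm.AnnotationLayer(id=None, image_id=img.id,
                                               agent_id=1))
    for wkt in scene.truth_polygons["islet"]:
        store.add_annotation(cm.Annotation(id=None, image_id=img.id,
                                           layer_id=layer.id, geometry=wkt,
                                           term_ids={1}))
    if n_terms > 1:
        store.add_annotation(cm.Annotation(
            id=None, image_id=img.id, layer_id=layer.id,
            geometry=f"POLYGON ((2 2, 60 2, 60 60, 2 60, 2 2))", term_ids={2}))
    return store, img.id, layer.id


@pytest.fixture(scope="module")
def scene():
    return fixtures.generate_tissue_image(320, 320, 2, (40, 60), seed=5)


@pytest.fixture(scope="module")
def trained(scene):
    store, image_id, _ = two_texture_store(scene)
    samples = S.assemble_training_set(store, {image_id: scene.image},
                                      {1: 1, 2: 0}, level=0, window_size=12,
                                      n_subwindows=300, seed=9)
    model = S.train_segmenter(samples, n_trees=15, seed=9)
    return store, image_id, samples, model


class TestAssembleTrainingSet:
    def test_fixed_seed_reproducible(self, scene):
        store, image_id, _ = two_texture_store(scene)
        kw = dict(level=0, window_size=12, n_subwindows=50, seed=4)
        s1 = S.assemble_training_set(store, {image_id: scene.image}, {1: 1}, **kw)
        s2 = S.assemble_training_set(store, {image_id: scene.image}, {1: 1}, **kw)
        for a, b in zip(s1, s2):
            assert a.source == b.source
            assert np.array_equal(a.pixels, b.pixels)
            assert np.array_equal(a.labels, b.labels)

    def test_fully_covered_image_all_labels_foreground(self):
        store = cm.EntityStore()
        ont = store.add_ontology(cm.Ontology(id=None, name="o",
                                             terms=[cm.Term(1, "tumor")]))
        proj = store.add_project(cm.Project(id=None, name="p", ontology_id=ont.id))
        img = store.add_image(cm.ImageInstance(id=None, project_id=proj.id,
                                               name="i", width=64, height=64))
        layer = store.add_layer(cm.AnnotationLayer(id=None, image_id=img.id,
                                                   agent_id=1))
        store.add_annotation(cm.Annotation(
            id=None, image_id=img.id, layer_id=layer.id,
            geometry="POLYGON ((0 0, 64 0, 64 64, 0 64, 0 0))", term_ids={1}))
        pix = np.full((64, 64), 200, dtype=np.uint8)
        samples = S.assemble_training_set(store, {img.id: pix}, {1: 1},
                                          window_size=8, n_subwindows=20, seed=0)
        for s in samples:
            assert (s.labels == 1).all()

    def test_zero_subwindows_rejected(self, scene):
        store, image_id, _ = two_texture_store(scene)
        with pytest.raises(ValidationError):
            S.assemble_training_set(store, {image_id: scene.image}, {1: 1},
                                    n_subwindows=0)

    def test_missing_class_annotations_rejected(self, scene):
        store, image_id, _ = two_texture_store(scene)
        with pytest.raises(ValidationError, match="99"):
            S.assemble_training_set(store, {image_id: scene.image},
                                    {1: 1, 99: 2}, n_subwindows=10)


class TestTrainSegmenter:
    def test_separable_textures_reach_perfect_training_accuracy(self, trained):
        _, _, samples, model = trained
        X, Y = S._flatten(samples)
        assert (model.ensemble.predict(X) == Y).mean() == 1.0

    def test_same_seed_identical_predictions(self, scene, trained):
        store, image_id, samples, model = trained
        model2 = S.train_segmenter(samples, n_trees=15, seed=9)
        tile = scene.image[:40, :40]
        m1 = S.predict_confidence(model, tile, stride=12)
        m2 = S.predict_confidence(model2, tile, stride=12)
        assert np.array_equal(m1.probabilities, m2.probabilities)

    def test_single_class_rejected(self):
        pix = np.zeros((8, 8)); lab = np.zeros((8, 8), dtype=int)
        samples = [S.SubwindowSample(pix, lab, (0, 0, 0, 0))] * 5
        with pytest.raises(ValidationError):
            S.train_segmenter(samples, n_trees=5)

    def test_zero_trees_rejected(self, trained):
        _, _, samples, _ = trained
        with pytest.raises(ValidationError):
            S.train_segmenter(samples, n_trees=0)


class TestPredictConfidence:
    def test_stride_equal_window_gives_unit_coverage(self, trained):
        _, _, _, model = trained
        tile = np.zeros((48, 48), dtype=np.uint8)  # multiple of window 12
        cmap = S.predict_confidence(model, tile, stride=12)
        assert (cmap.coverage == 1).all()

    def test_tile_smaller_than_window_rejected(self, trained):
        _, _, _, model = trained
        with pytest.raises(ValidationError):
            S.predict_confidence(model, np.zeros((8, 8)), stride=4)

    def test_probabilities_in_unit_interval_and_covered(self, scene, trained):
        _, _, _, model = trained
        cmap = S.predict_confidence(model, scene.image[:64, :64], stride=5)
        assert cmap.probabilities.min() >= 0 and cmap.probabilities.max() <= 1
        assert (cmap.coverage >= 1).all()

    def test_matches_naive_per_pixel_averaging_oracle(self, scene, trained):
        _, _, _, model = trained
        tile = scene.image[100:148, 100:148].astype(np.float32)
        stride, w = 7, model.window_size
        cmap = S.predict_confidence(model, tile, stride=stride)
        # naive loop: one window at a time, accumulate per-pixel means
        prob = np.zeros(tile.shape); cov = np.zeros(tile.shape)
        ys = list(range(0, tile.shape[0] - w + 1, stride))
        xs = list(range(0, tile.shape[1] - w + 1, stride))
        if ys[-1] != tile.shape[0] - w: ys.append(tile.shape[0] - w)
        if xs[-1] != tile.shape[1] - w: xs.append(tile.shape[1] - w)
        for y in ys:
            for x in xs:
                win = tile[y:y + w, x:x + w].reshape(1, -1)
                proba = model.ensemble.predict_proba(win)
                for o in range(w * w):
                    cls = model.ensemble.classes_[o]
                    p_bg = proba[o][0][list(cls).index(0)] if 0 in cls else 0.0
                    prob[y + o // w, x + o % w] += 1.0 - p_bg
                cov[y:y + w, x:x + w] += 1
        assert np.allclose(cmap.probabilities, prob / cov, atol=1e-12)
        assert np.array_equal(cmap.coverage, cov)


class TestSegmentImage:
    def test_threshold_above_max_confidence_gives_empty(self, scene, trained):
        _, _, _, model = trained
        assert S.segment_image(model, scene.image[:64, :64], threshold=1.0,
                               stride=6) == [] or all(
            c >= 1.0 for _, c in S.segment_image(model, scene.image[:64, :64],
                                                 threshold=1.0, stride=6))

    def test_min_area_larger_than_components_gives_empty(self, scene, trained):
        _, _, _, model = trained
        out = S.segment_image(model, scene.image, threshold=0.5,
                              min_area=1e9, stride=8)
        assert out == []

    def test_invalid_threshold_rejected(self, scene, trained):
        _, _, _, model = trained
        for bad in (0.0, 1.5, -0.2):
            with pytest.raises(ValidationError):
                S.segment_image(model, scene.image, threshold=bad)

    def test_recovers_truth_components_with_high_dice(self, scene, trained):
        _, _, _, model = trained
        out = S.segment_image(model, scene.image, threshold=0.5, min_area=400,
                              stride=6)
        assert len(out) == len(scene.truth_polygons["islet"])
        metrics = S.evaluate_segmentation([w for w, _ in out],
                                          scene.truth_polygons["islet"])
        assert metrics["dice"] >= 0.85

    def test_output_polygons_valid_and_disjoint(self, scene, trained):
        import shapely.wkt
        _, _, _, model = trained
        out = S.segment_image(model, scene.image, threshold=0.5, min_area=400,
                              stride=6)
        geoms = [shapely.wkt.loads(w) for w, _ in out]
        assert all(g.is_valid for g in geoms)
        for i in range(len(geoms)):
            for j in range(i + 1, len(geoms)):
                assert geoms[i].intersection(geoms[j]).area == 0

    def test_deterministic_given_model_and_fixture(self, scene, trained):
        _, _, _, model = trained
        a = S.segment_image(model, scene.image, threshold=0.5, min_area=400,
                            stride=8)
        b = S.segment_image(model, scene.image, threshold=0.5, min_area=400,
                            stride=8)
        assert a == b


class TestEvaluate:
    def test_identical_polygons_dice_one(self):
        sq = "POLYGON ((0 0, 2 0, 2 2, 0 2, 0 0))"
        assert S.evaluate_segmentation([sq], [sq])["dice"] == 1.0

    def test_disjoint_polygons_dice_zero(self):
        a = "POLYGON ((0 0, 1 0, 1 1, 0 1, 0 0))"
        b = "POLYGON ((5 5, 6 5, 6 6, 5 6, 5 5))"
        assert S.evaluate_segmentation([a], [b])["dice"] == 0.0

    def test_partial_overlap_inclusion_exclusion(self):
        a = "POLYGON ((0 0, 2 0, 2 2, 0 2, 0 0))"
        b = "POLYGON ((1 1, 3 1, 3 3, 1 3, 1 1))"
        assert S.evaluate_segmentation([a], [b])["dice"] == pytest.approx(0.25)

    def test_both_empty_is_perfect_by_convention(self):
        out = S.evaluate_segmentation([], [])
        assert out["dice"] == 1.0 and out["iou"] == 1.0


class TestPersistence:
    def test_save_load_round_trip_predictions(self, scene, trained, tmp_path):
        _, _, _, model = trained
        S.save_model(model, tmp_path / "model")
        loaded = S.load_model(tmp_path / "model")
        tile = scene.image[:36, :36]
        assert np.array_equal(
            S.predict_confidence(model, tile, stride=12).probabilities,
            S.predict_confidence(loaded, tile, stride=12).probabilities)
        assert loaded.classes == model.classes


class TestMaskToPolygons:
    def test_staircase_area_equals_pixel_count(self, rng):
        mask = rng.random((40, 40)) > 0.7
        polys, labels = S.mask_to_polygons(mask)
        assert sum(p.area for _, p in polys) == mask.sum()

    def test_eight_connectivity_joins_diagonals(self):
        mask = np.eye(5, dtype=bool)
        polys, _ = S.mask_to_polygons(mask)
        assert len(polys) == 1
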