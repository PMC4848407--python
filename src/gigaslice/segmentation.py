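"""Semantic segmentation as multi-output pixel classification.

A subwindow of raw pixel intensities is the descriptor and the label of
*every* pixel in the window is the (multi-output) target, so a single tree
ensemble predicts a full label patch per subwindow.  Training subwindows
are sampled where windows overlap expert-annotated geometry; at prediction
time overlapping subwindows are placed on a stride grid and their
per-pixel foreground votes are averaged into a confidence map, which is
thresholded, vectorized into staircase polygons (area-conserving, no
smoothing) and mapped back to level-0 coordinates.

Class code 0 is always background (pixels not covered by any annotation of
a mapped term); the foreground probability of a pixel is 1 - P(background).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import joblib
import numpy as np
import scipy.ndimage as ndi
import shapely.wkt
from shapely.geometry import box
from shapely.ops import unary_union
from sklearn.ensemble import ExtraTreesClassifier

from .core_model import ValidationError
from . import geometry_ops
from . import pyramid as _pyr

DEFAULT_WINDOW = 24
DEFAULT_N_SUBWINDOWS = 50_000
DEFAULT_N_TREES = 100

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class SubwindowSample:
    pixels: np.ndarray   # w x w (x channels) raw intensities
    labels: np.ndarray   # w x w class codes (0 = background)
    source: tuple        # (image_id, level, x, y)


@dataclass
class SegmentationModel:
    ensemble: ExtraTreesClassifier
    window_size: int
    classes: list        # ordered term ids, index 0 = background (0)
    training_level: int
    n_trees: int
    seed: int


@dataclass
class ConfidenceMap:
    probabilities: np.ndarray  # per-pixel foreground probability in [0, 1]
    coverage: np.ndarray       # per-pixel count of contributing subwindows


# ---------------------------------------------------------------------------
# Level image access (pyramid- or array-backed)
# ---------------------------------------------------------------------------

def _level_image(source, level: int) -> np.ndarray:
    """Full image at a pyramid level from a TilePyramid or a raw array."""
    if isinstance(source, _pyr.TilePyramid):
        return _pyr.get_level_image(source, level)
    arr = np.asarray(source)
    for _ in range(level):
        arr = _pyr.reduce_2x(arr, "mean")
    return arr


# ---------------------------------------------------------------------------
# Training set assembly
# ---------------------------------------------------------------------------

def assemble_training_set(store, sources, term_map, level=0,
                          window_size=DEFAULT_WINDOW,
                          n_subwindows=DEFAULT_N_SUBWINDOWS, seed=0) -> list:
    """Sample labeled subwindows from annotated images.

    ``sources`` maps image_id to a TilePyramid or raw array; ``term_map``
    maps ontology term id to a class code.  Code 0 marks explicit
    background exemplars (e.g. "non-tumor" annotations): they guide window
    placement but label their pixels background, exactly like unannotated
    pixels.  Subwindow top-left corners are drawn uniformly (seeded) from
    positions where the window overlaps annotated geometry of any mapped
    term; per-pixel labels come from the by-term rasterized mask with
    unannotated pixels labeled 0.
    """
    if n_subwindows <= 0:
        raise ValidationError("n_subwindows must be >= 1")
    if any(code < 0 for code in term_map.values()):
        raise ValidationError("class codes must be >= 0 (0 is background)")
    per_image: dict[int, list] = {}
    seen_terms: set = set()
    for ann in store.annotations.values():
        mapped = ann.term_ids & set(term_map)
        if mapped and ann.image_id in sources:
            tid = max(mapped)
            per_image.setdefault(ann.image_id, []).append(
                (ann.id, ann.geometry, term_map[tid]))
            seen_terms |= mapped
    missing = set(term_map) - seen_terms
    if missing:
        raise ValidationError(f"no annotations for mapped terms {sorted(missing)}")
    if len({term_map[t] for t in seen_terms}) + 1 < 2:
        raise ValidationError("need annotations for at least one class")

    rng = np.random.default_rng(seed)
    image_ids = sorted(per_image)
    quota = [n_subwindows // len(image_ids)] * len(image_ids)
    for i in range(n_subwindows % len(image_ids)):
        quota[i] += 1
    samples: list[SubwindowSample] = []
    for image_id, n_want in zip(image_ids, quota):
        if n_want == 0:
            continue
        img = _level_image(sources[image_id], level)
        h, w = img.shape[:2]
        if h < window_size or w < window_size:
            raise ValidationError(
                f"window {window_size} does not fit image {image_id} at level {level}")
        region = _pyr.RegionSpec(level, 0, 0, w, h)
        items = [(_pyr.map_coordinates(g, 0, level), code)
                 for _, g, code in sorted(per_image[image_id])]
        fg_items = [(g, code) for g, code in items if code > 0]
        labels = _pyr.render_annotation_mask((w, h), fg_items, region,
                                             mode="by-term") if fg_items \
            else np.zeros((h, w), dtype=np.int64)
        covered = _pyr.render_annotation_mask(
            (w, h), [g for g, _ in items], region, mode="binary")
        # valid top-lefts: window contains >= 1 annotated pixel (integral image)
        ann_mask = covered.astype(np.int64)
        ii = np.pad(ann_mask.cumsum(0).cumsum(1), ((1, 0), (1, 0)))
        k = window_size
        wsum = (ii[k:, k:] - ii[:-k, k:] - ii[k:, :-k] + ii[:-k, :-k])
        valid = np.flatnonzero(wsum > 0)
        if valid.size == 0:
            raise ValidationError(f"no annotated region at level {level} "
                                  f"in image {image_id}")
        picks = rng.choice(valid, size=n_want, replace=True)
        ys, xs = np.unravel_index(picks, wsum.shape)
        for y, x in zip(ys.tolist(), xs.tolist()):
            samples.append(SubwindowSample(
                pixels=img[y:y + k, x:x + k].copy(),
                labels=labels[y:y + k, x:x + k].astype(np.int64),
                source=(image_id, level, x, y)))
    return samples


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _flatten(samples):
    X = np.stack([s.pixels.reshape(-1) for s in samples]).astype(np.float32)
    Y = np.stack([s.labels.reshape(-1) for s in samples])
    return X, Y


def train_segmenter(samples, n_trees=DEFAULT_N_TREES, max_features="sqrt",
                    min_samples_leaf=1, seed=0, training_level=0,
                    classes=None) -> SegmentationModel:
    """Fit the multi-output tree ensemble on labeled subwindows."""
    if n_trees <= 0:
        raise ValidationError("n_trees must be >= 1")
    if not samples:
        raise ValidationError("empty training set")
    X, Y = _flatten(samples)
    present = np.unique(Y)
    if present.size < 2:
        raise ValidationError("training labels contain a single class")
    est = ExtraTreesClassifier(
        n_estimators=n_trees, max_features=max_features,
        min_samples_leaf=min_samples_leaf, random_state=seed, n_jobs=1)
    est.fit(X, Y)
    if classes is None:
        classes = [int(c) for c in present if c != 0]
    window = samples[0].pixels.shape[0]
    return SegmentationModel(ensemble=est, window_size=window,
                             classes=[0] + list(classes),
                             training_level=training_level,
                             n_trees=n_trees, seed=seed)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _grid_positions(extent: int, window: int, stride: int) -> np.ndarray:
    xs = list(range(0, extent - window + 1, stride))
    if xs[-1] != extent - window:
        xs.append(extent - window)  # edge snap so borders are covered
    return np.asarray(xs)


def _foreground_votes(est, X: np.ndarray, n_outputs: int) -> np.ndarray:
    """Per-output foreground probability 1 - P(background) for a batch."""
    proba = est.predict_proba(X)
    if n_outputs == 1:
        proba = [proba]
    fg = np.empty((X.shape[0], n_outputs))
    classes = est.classes_ if n_outputs > 1 else [est.classes_]
    for o in range(n_outputs):
        cls = classes[o]
        bg = np.flatnonzero(cls == 0)
        fg[:, o] = 1.0 - proba[o][:, bg[0]] if bg.size else 1.0
    return fg


def predict_confidence(model: SegmentationModel, tile: np.ndarray,
                       stride: int, batch: int = 4096) -> ConfidenceMap:
    """Averaged per-pixel foreground probability over overlapping subwindows.

    Subwindows sit on a stride grid plus edge-snapped rows/columns; each
    pixel's probability is the mean over all covering subwindows (and over
    the trees) of the foreground vote.
    """
    w = model.window_size
    H, W = tile.shape[:2]
    if H < w or W < w:
        raise ValidationError(f"tile {W}x{H} smaller than window {w}")
    ys = _grid_positions(H, w, stride)
    xs = _grid_positions(W, w, stride)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    tops = np.column_stack([yy.ravel(), xx.ravel()])
    prob_sum = np.zeros((H, W))
    coverage = np.zeros((H, W), dtype=np.int64)
    tile_f = np.asarray(tile, dtype=np.float32)
    n_feat = w * w * (1 if tile_f.ndim == 2 else tile_f.shape[2])
    for start in range(0, len(tops), batch):
        chunk = tops[start:start + batch]
        X = np.stack([tile_f[y:y + w, x:x + w].reshape(-1) for y, x in chunk])
        assert X.shape[1] == n_feat
        fg = _foreground_votes(model.ensemble, X, w * w)
        for (y, x), votes in zip(chunk, fg):
            prob_sum[y:y + w, x:x + w] += votes.reshape(w, w)
            coverage[y:y + w, x:x + w] += 1
    probs = np.divide(prob_sum, coverage, out=np.zeros_like(prob_sum),
                      where=coverage > 0)
    return ConfidenceMap(probabilities=probs, coverage=coverage)


# ---------------------------------------------------------------------------
# Vectorization
# ---------------------------------------------------------------------------

def mask_to_polygons(mask: np.ndarray):
    """Exact staircase polygons of 8-connected components of a binary mask.

    Each component becomes the union of its row-run rectangles, so polygon
    area equals the pixel count exactly.  Returns (polygons, label image).
    """
    labels, n = ndi.label(mask, structure=_EIGHT)
    polys = []
    for idx, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        sub = labels[sl] == idx
        y_off, x_off = sl[0].start, sl[1].start
        boxes = []
        for i, rowv in enumerate(sub):
            d = np.diff(np.concatenate([[0], rowv.astype(np.int8), [0]]))
            for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
                boxes.append(box(x_off + s, y_off + i, x_off + e, y_off + i + 1))
        polys.append((idx, unary_union(boxes)))
    return polys, labels


def segment_image(model: SegmentationModel, source, level=0, threshold=0.5,
                  min_area=0, fill_holes=False, stride=None) -> list:
    """Segment an image at one pyramid level into annotation polygons.

    Returns ``[(WKT polygon in level-0 coordinates, mean confidence), ...]``.
    The confidence map is thresholded (probability >= threshold), connected
    components (8-connectivity) are vectorized into staircase polygons,
    components smaller than ``min_area`` pixels at the prediction level are
    dropped, holes optionally filled, and coordinates mapped to level 0.
    """
    if not (0 < threshold <= 1):
        raise ValidationError("threshold must be in (0, 1]")
    if stride is None:
        stride = max(1, model.window_size // 2)
    img = _level_image(source, level)
    cmap = predict_confidence(model, img, stride)
    fg_mask = cmap.probabilities >= threshold
    polys, labels = mask_to_polygons(fg_mask)
    results = []
    for idx, poly in polys:
        if poly.area < min_area:
            continue
        if fill_holes:
            poly = geometry_ops.fill_internal_holes(poly)
        comp_pixels = cmap.probabilities[labels == idx]
        conf = float(comp_pixels.mean()) if comp_pixels.size else 0.0
        results.append((_pyr.map_coordinates(poly.wkt, level, 0), conf))
    return results


def evaluate_segmentation(predicted, truth) -> dict:
    """Area-overlap metrics between predicted and true polygon sets.

    Dice = 2|P∩T| / (|P| + |T|); both sets empty is perfect agreement
    (dice = iou = 1) by convention.
    """
    def _union(geoms):
        gg = [shapely.wkt.loads(g) if isinstance(g, str) else g for g in geoms]
        return unary_union(gg) if gg else None
    P, T = _union(predicted), _union(truth)
    pa = P.area if P is not None else 0.0
    ta = T.area if T is not None else 0.0
    if pa == 0 and ta == 0:
        return {"dice": 1.0, "iou": 1.0, "predicted_area": 0.0, "truth_area": 0.0}
    inter = P.intersection(T).area if (P is not None and T is not None) else 0.0
    union = pa + ta - inter
    return {"dice": 2 * inter / (pa + ta), "iou": inter / union if union else 1.0,
            "predicted_area": pa, "truth_area": ta}


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: SegmentationModel, dirpath) -> None:
    """Persist as a versioned archive: manifest JSON + serialized ensemble."""
    os.makedirs(dirpath, exist_ok=True)
    manifest = {"format_version": 1, "window_size": model.window_size,
                "classes": model.classes, "training_level": model.training_level,
                "n_trees": model.n_trees, "seed": model.seed}
    with open(os.path.join(dirpath, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    joblib.dump(model.ensemble, os.path.join(dirpath, "ensemble.joblib"))


def load_model(dirpath) -> SegmentationModel:
    with open(os.path.join(dirpath, "manifest.json")) as fh:
        m = json.load(fh)
    est = joblib.load(os.path.join(dirpath, "ensemble.joblib"))
    return SegmentationModel(ensemble=est, window_size=m["window_size"],
                             classes=m["classes"],
                             training_level=m["training_level"],
                             n_trees=m["n_trees"], seed=m["seed"])
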