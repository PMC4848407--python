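"""Patch-based landmark detection and morphometric measurement.

A landmark detector is a binary tree-ensemble classifier on raw intensity
patches: positives are patches centered within radius R of the annotated
landmark, negatives are sampled far from it.  Detection scans a new image
on a stride grid and returns the most landmark-like patch center.  The
module also covers the proofreading gesture (moving a mispositioned
detection, preserving the original with provenance) and pairwise distance
measurements between named landmarks.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier

from .core_model import ValidationError

DEFAULT_PATCH = 33
DEFAULT_RADIUS = 5


@dataclass
class LandmarkAnnotation:
    image_id: int
    landmark_id: str
    x: float
    y: float
    source: str = "manual"       # manual | detected | reviewed
    original: "LandmarkAnnotation | None" = None
    reviewer_id: int | None = None


@dataclass
class LandmarkModel:
    ensemble: ExtraTreesClassifier
    patch_size: int
    positive_radius: int
    detection_level: int
    seed: int


# ---------------------------------------------------------------------------
# Patch sampling
# ---------------------------------------------------------------------------

def sample_landmark_patches(images, landmark_xy, patch_size=DEFAULT_PATCH,
                            R=DEFAULT_RADIUS, n_negatives_per_image=50,
                            min_negative_distance=20, seed=0):
    """Positive / negative patch sets around an annotated landmark.

    ``images`` is a sequence of 2D arrays and ``landmark_xy`` the matching
    sequence of (x, y) truth positions (None to skip an image).  Positives
    are every integer patch center within distance <= R of the landmark;
    negatives are seeded uniform centers at distance >= min_negative_distance.
    Patches lie entirely inside their image.  Returns (patches, labels).
    """
    if patch_size % 2 == 0:
        raise ValidationError("patch_size must be odd")
    hw = patch_size // 2
    rng = np.random.default_rng(seed)
    patches, labels = [], []
    used = 0
    for img, xy in zip(images, landmark_xy):
        if xy is None:
            continue
        img = np.asarray(img)
        h, w = img.shape[:2]
        lx, ly = xy
        diag = math.hypot(w, h)
        if min_negative_distance > diag:
            raise ValidationError("min_negative_distance exceeds image diagonal")
        used += 1
        for cy in range(max(hw, int(ly) - R), min(h - hw - 1, int(ly) + R) + 1):
            for cx in range(max(hw, int(lx) - R), min(w - hw - 1, int(lx) + R) + 1):
                if math.hypot(cx - lx, cy - ly) <= R:
                    patches.append(img[cy - hw:cy + hw + 1, cx - hw:cx + hw + 1])
                    labels.append(1)
        drawn, tries = 0, 0
        while drawn < n_negatives_per_image:
            tries += 1
            if tries > 100 * n_negatives_per_image:
                raise ValidationError("cannot draw negatives at the requested distance")
            cx = int(rng.integers(hw, w - hw))
            cy = int(rng.integers(hw, h - hw))
            if math.hypot(cx - lx, cy - ly) >= min_negative_distance:
                patches.append(img[cy - hw:cy + hw + 1, cx - hw:cx + hw + 1])
                labels.append(0)
                drawn += 1
    if used == 0:
        raise ValidationError("no usable training image has the landmark")
    return patches, np.asarray(labels)


def train_landmark_model(patches, labels, n_trees=50, seed=0,
                         positive_radius=DEFAULT_RADIUS,
                         detection_level=0) -> LandmarkModel:
    """Fit the near-landmark patch classifier."""
    if n_trees <= 0:
        raise ValidationError("n_trees must be >= 1")
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValidationError("need both positive and negative patches")
    X = np.stack([np.asarray(p, dtype=np.float32).reshape(-1) for p in patches])
    est = ExtraTreesClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    est.fit(X, labels)
    patch = np.asarray(patches[0]).shape[0]
    return LandmarkModel(ensemble=est, patch_size=patch,
                         positive_radius=positive_radius,
                         detection_level=detection_level, seed=seed)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_landmark(model: LandmarkModel, image, stride=2, batch=8192):
    """Most landmark-like position on a stride grid: (x, y, confidence).

    Candidate centers are scanned row-major so probability ties resolve to
    the smallest y, then the smallest x.  Coordinates are returned in the
    pixel frame of the scanned image (level-0 when scanning level 0).
    """
    img = np.asarray(image, dtype=np.float32)
    h, w = img.shape[:2]
    p = model.patch_size
    if h < p or w < p:
        raise ValidationError(f"image {w}x{h} smaller than patch {p}")
    hw = p // 2
    ys = np.arange(hw, h - hw, stride)
    xs = np.arange(hw, w - hw, stride)
    centers = [(int(cy), int(cx)) for cy in ys for cx in xs]  # row-major: y then x
    pos_col = int(np.flatnonzero(model.ensemble.classes_ == 1)[0])
    best_prob, best_yx = -1.0, None
    for start in range(0, len(centers), batch):
        chunk = centers[start:start + batch]
        X = np.stack([img[cy - hw:cy + hw + 1, cx - hw:cx + hw + 1].reshape(-1)
                      for cy, cx in chunk])
        probs = model.ensemble.predict_proba(X)[:, pos_col]
        i = int(np.argmax(probs))  # first max within the chunk
        if probs[i] > best_prob:
            best_prob, best_yx = float(probs[i]), chunk[i]
    cy, cx = best_yx
    return float(cx), float(cy), best_prob


# ---------------------------------------------------------------------------
# Proofreading and measurement
# ---------------------------------------------------------------------------

def move_landmark(annotation: LandmarkAnnotation, new_xy, reviewer_id,
                  image_extent=None) -> LandmarkAnnotation:
    """Reviewed copy at a corrected position; the original is preserved."""
    x, y = float(new_xy[0]), float(new_xy[1])
    if image_extent is not None:
        w, h = image_extent
        if not (0 <= x < w and 0 <= y < h):
            raise ValidationError(f"position ({x}, {y}) outside image {w}x{h}")
    return LandmarkAnnotation(
        image_id=annotation.image_id, landmark_id=annotation.landmark_id,
        x=x, y=y, source="reviewed", original=annotation,
        reviewer_id=reviewer_id)


def measure_distances(landmarks: dict, pairs, resolution=None) -> list:
    """Euclidean distances between named landmark pairs.

    ``landmarks`` maps landmark_id -> (x, y); ``resolution`` (µm/px) adds a
    physical distance.  A pair with a missing endpoint yields an error
    entry instead of aborting the batch.
    """
    out = []
    for a, b in pairs:
        entry = {"pair": (a, b)}
        if a not in landmarks or b not in landmarks:
            entry["error"] = "missing endpoint"
        else:
            d = math.dist(landmarks[a], landmarks[b])
            entry["distance_px"] = d
            entry["distance_um"] = d * resolution if resolution is not None else None
        out.append(entry)
    return out


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def export_landmarks_csv(annotations, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "landmark", "x", "y", "source"])
        for a in annotations:
            writer.writerow([a.image_id, a.landmark_id, a.x, a.y, a.source])


def import_landmarks_csv(path) -> list:
    with open(path, newline="") as fh:
        return [LandmarkAnnotation(image_id=int(r["image"]),
                                   landmark_id=r["landmark"],
                                   x=float(r["x"]), y=float(r["y"]),
                                   source=r["source"])
                for r in csv.DictReader(fh)]
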