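"""Seeded synthetic scenes with exact ground truth.

Every analysis module in this package is exercised on generated data whose
truth is known by construction: textured "tissue" images with polygonal
islets, spot fields inside regions of interest, marker images for landmark
detection, texture galleries for retrieval and multi-observer label tables.
Identical (generator, parameters, seed) always yields a bit-identical
scene.

Textures are Gaussian noise fields with distinct means (foreground /
background separated by several noise standard deviations), deliberately
simple so recognition tests probe the pipeline rather than learner
strength; none of this emulates stain chemistry or real histology texture.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
import shapely.wkt
from shapely.geometry import Point, Polygon

from . import pyramid as _pyr


@dataclass
class FixtureScene:
    image: np.ndarray
    truth_polygons: dict = field(default_factory=dict)   # term/name -> [WKT]
    truth_points: dict = field(default_factory=dict)     # roi index -> [(x, y)]
    truth_landmarks: dict = field(default_factory=dict)  # name -> (x, y)
    seed: int = 0
    params: dict = field(default_factory=dict)


def _noise(rng, shape, mean, sd):
    return np.clip(rng.normal(mean, sd, shape), 0, 255)


def _disc_polygon(cx, cy, r, n_vertices=64) -> Polygon:
    ang = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    return Polygon(np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)]))


# ---------------------------------------------------------------------------
# Tissue scenes (area quantification / segmentation)
# ---------------------------------------------------------------------------

def generate_tissue_image(width=2048, height=2048, n_islets=5,
                          islet_radius_range=(80, 160), fg_mean=170.0,
                          bg_mean=80.0, noise_sd=10.0, seed=0) -> FixtureScene:
    """Textured background with non-overlapping polygonal foreground islets.

    Foreground and background are Gaussian textures whose means differ by
    several noise standard deviations (separable by intensity alone).
    ``truth_polygons['islet']`` holds the exact blob outlines.
    """
    if abs(fg_mean - bg_mean) < 4 * noise_sd:
        raise ValueError("texture means must be separated by >= 4 noise sd")
    rng = np.random.default_rng(seed)
    img = _noise(rng, (height, width), bg_mean, noise_sd)
    rmin, rmax = islet_radius_range
    polys: list[Polygon] = []
    attempts = 0
    while len(polys) < n_islets:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not place non-overlapping islets")
        r = rng.uniform(rmin, rmax)
        cx = rng.uniform(r + 2, width - r - 2)
        cy = rng.uniform(r + 2, height - r - 2)
        cand = _disc_polygon(cx, cy, r)
        if all(cand.distance(p) > 4 for p in polys):
            polys.append(cand)
    if polys:
        mask = _pyr.render_annotation_mask(
            (width, height), [p.wkt for p in polys],
            _pyr.RegionSpec(0, 0, 0, width, height), mode="binary")
        fg = _noise(rng, (height, width), fg_mean, noise_sd)
        img = np.where(mask.astype(bool), fg, img)
    return FixtureScene(
        image=img.astype(np.uint8),
        truth_polygons={"islet": [p.wkt for p in polys]},
        seed=seed,
        params=dict(width=width, height=height, n_islets=n_islets,
                    islet_radius_range=tuple(islet_radius_range),
                    fg_mean=fg_mean, bg_mean=bg_mean, noise_sd=noise_sd))


# ---------------------------------------------------------------------------
# Spot scenes (object counting)
# ---------------------------------------------------------------------------

def generate_spot_image(rois, spots_per_roi, spot_radius=4, image_size=None,
                        bg_mean=200.0, noise_sd=5.0, seed=0) -> FixtureScene:
    """Dark disks at seeded positions strictly inside each ROI polygon.

    Spots keep a margin of ``spot_radius`` from the ROI boundary so none
    straddles it; ``truth_points`` maps ROI index to spot centers.
    """
    rois = [shapely.wkt.loads(r) if isinstance(r, str) else r for r in rois]
    if len(spots_per_roi) != len(rois):
        raise ValueError("spots_per_roi must match rois")
    if image_size is None:
        maxx = max(r.bounds[2] for r in rois)
        maxy = max(r.bounds[3] for r in rois)
        image_size = (int(math.ceil(maxx)) + 8, int(math.ceil(maxy)) + 8)
    w, h = image_size
    rng = np.random.default_rng(seed)
    img = _noise(rng, (h, w), bg_mean, noise_sd)
    yy, xx = np.mgrid[0:h, 0:w]
    truth_points: dict[int, list] = {}
    for i, (roi, n) in enumerate(zip(rois, spots_per_roi)):
        safe = roi.buffer(-(spot_radius + 1))
        if n > 0 and safe.is_empty:
            raise ValueError(f"ROI {i} too small for spot radius {spot_radius}")
        pts = []
        minx, miny, maxx, maxy = roi.bounds
        while len(pts) < n:
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            if safe.covers(Point(x, y)):
                pts.append((x, y))
                img[(xx - x) ** 2 + (yy - y) ** 2 <= spot_radius ** 2] = 20
        truth_points[i] = pts
    return FixtureScene(
        image=img.astype(np.uint8),
        truth_polygons={"roi": [r.wkt for r in rois]},
        truth_points=truth_points, seed=seed,
        params=dict(spots_per_roi=list(spots_per_roi), spot_radius=spot_radius,
                    image_size=(w, h)))


# ---------------------------------------------------------------------------
# Landmark scenes
# ---------------------------------------------------------------------------

def cross_marker(size=15, intensity=255) -> np.ndarray:
    """Bright cross template used as the default landmark marker."""
    m = np.zeros((size, size), dtype=np.float64)
    mid = size // 2
    m[mid - 1:mid + 2, :] = intensity
    m[:, mid - 1:mid + 2] = intensity
    return m


def generate_landmark_images(n_images=20, image_size=(256, 256),
                             marker_template=None, jitter_sd=30.0,
                             background_noise_sd=10.0, bg_mean=80.0,
                             seed=0) -> list:
    """Images each containing one marker at a seeded jittered position.

    The jitter is a truncated Gaussian around the image center;
    ``truth_landmarks['landmark']`` records the exact marker center.
    """
    if marker_template is None:
        marker_template = cross_marker()
    mh, mw = marker_template.shape
    w, h = image_size
    rng = np.random.default_rng(seed)
    scenes = []
    for _ in range(n_images):
        img = _noise(rng, (h, w), bg_mean, background_noise_sd)
        cx = float(np.clip(w / 2 + rng.normal(0, jitter_sd), mw // 2 + 1,
                           w - mw // 2 - 2))
        cy = float(np.clip(h / 2 + rng.normal(0, jitter_sd), mh // 2 + 1,
                           h - mh // 2 - 2))
        x0, y0 = int(round(cx)) - mw // 2, int(round(cy)) - mh // 2
        patch = img[y0:y0 + mh, x0:x0 + mw]
        img[y0:y0 + mh, x0:x0 + mw] = np.where(marker_template > 0,
                                               marker_template, patch)
        scenes.append(FixtureScene(
            image=img.astype(np.uint8),
            truth_landmarks={"landmark": (float(round(cx)), float(round(cy)))},
            seed=seed,
            params=dict(image_size=(w, h), jitter_sd=jitter_sd)))
    return scenes


# ---------------------------------------------------------------------------
# Texture gallery (classification / retrieval)
# ---------------------------------------------------------------------------

def _texture(kind, shape, rng, noise_sd=12.0):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    if kind == 0:    # horizontal grating
        base = 128 + 90 * np.sin(2 * math.pi * yy / 8.0)
    elif kind == 1:  # vertical grating
        base = 128 + 90 * np.sin(2 * math.pi * xx / 8.0)
    elif kind == 2:  # checkerboard
        base = np.where(((xx // 6) + (yy // 6)) % 2 == 0, 40, 215)
    else:            # diagonal grating
        base = 128 + 90 * np.sin(2 * math.pi * (xx + yy) / 11.0)
    return np.clip(base + rng.normal(0, noise_sd, shape), 0, 255).astype(np.uint8)


def generate_texture_gallery(n_classes=4, crops_per_class=25, crop_size=48,
                             noise_sd=12.0, seed=0):
    """Structured-texture crop gallery: (crops, class labels).

    Classes differ in spatial structure (gratings of different orientation,
    a checkerboard), not in mean intensity, because mean/std-normalized
    descriptors are blind to flat intensity shifts.
    """
    rng = np.random.default_rng(seed)
    crops, labels = [], []
    for cls in range(n_classes):
        for _ in range(crops_per_class):
            crops.append(_texture(cls % 4, (crop_size, crop_size), rng, noise_sd))
            labels.append(cls)
    return crops, np.asarray(labels)


# ---------------------------------------------------------------------------
# Multi-observer label tables
# ---------------------------------------------------------------------------

def generate_observer_labels(truth_terms, observers=3, confusion=0.1,
                             categories=None, seed=0, path=None):
    """Simulated multi-observer assignments around known truth labels.

    Each observer reports the true term with probability ``1 - confusion``
    and a uniformly drawn *other* category otherwise.  Returns (and
    optionally writes as CSV ``object,observer,term``) the assignment rows.
    """
    truth_terms = list(truth_terms)
    if categories is None:
        categories = sorted(set(truth_terms))
    if len(categories) < 2 and confusion > 0:
        raise ValueError("need >= 2 categories to confuse labels")
    rng = np.random.default_rng(seed)
    rows = []
    for obj, truth in enumerate(truth_terms):
        for obs in range(observers):
            if rng.random() < confusion:
                others = [c for c in categories if c != truth]
                label = others[rng.integers(len(others))]
            else:
                label = truth
            rows.append((obj, obs, label))
    if path is not None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["object", "observer", "term"])
            writer.writerows(rows)
    return rows
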