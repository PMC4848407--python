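"""Object classification and incremental content-based retrieval.

Every annotation crop is summarized by a transparent descriptor — the crop
resampled to ``d x d`` and per-channel mean/std normalized — and retrieval
is exact incremental nearest-neighbour search in that descriptor space
(Euclidean distance, ties broken by insertion order).  Term suggestion is
a majority vote over the k nearest labeled neighbours.  The descriptor and
search strategy are deliberately simple and replaceable; the module
contract is the incremental, on-the-fly ranking and suggestion behaviour.

A seeded tree ensemble over the same descriptors provides supervised
object classification into ontology terms.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize
from sklearn.ensemble import ExtraTreesClassifier

from .core_model import ValidationError

DEFAULT_RESAMPLE = 32


@dataclass
class CropDescriptor:
    vector: np.ndarray
    annotation_id: int


# ---------------------------------------------------------------------------
# Descriptor extraction
# ---------------------------------------------------------------------------

def extract_descriptor(crop: np.ndarray, d: int = DEFAULT_RESAMPLE,
                       annotation_id: int = -1) -> CropDescriptor:
    """Resample a crop to d x d and normalize each channel to mean 0, sd 1.

    A channel with zero spread keeps its (zero) centered values — the sd is
    clamped at 1 — so constant crops map to the zero vector.
    """
    arr = np.asarray(crop, dtype=np.float64)
    if arr.size == 0:
        raise ValidationError("empty crop")
    if arr.ndim == 2:
        arr = arr[:, :, None]
    out = resize(arr, (d, d, arr.shape[2]), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    for c in range(out.shape[2]):
        ch = out[:, :, c]
        sd = ch.std()
        out[:, :, c] = (ch - ch.mean()) / (sd if sd > 0 else 1.0)
    vec = out.ravel()
    if not np.all(np.isfinite(vec)):
        raise ValidationError("non-finite descriptor")
    return CropDescriptor(vector=vec, annotation_id=annotation_id)


# ---------------------------------------------------------------------------
# Incremental exact nearest-neighbour index
# ---------------------------------------------------------------------------

class RetrievalIndex:
    """Flat exact-NN index; adding never rebuilds or perturbs prior entries.

    Re-adding an annotation id replaces its vector in place (size
    unchanged); insertion order is preserved and breaks distance ties.
    """

    def __init__(self, dimensionality: int, distance: str = "euclidean"):
        if distance != "euclidean":
            raise ValueError("only euclidean distance is supported")
        self.dimensionality = dimensionality
        self.distance = distance
        self._ids: list[int] = []
        self._vectors: list[np.ndarray] = []
        self._row_of: dict[int, int] = {}

    def __len__(self) -> int:
        return len(self._ids)

    @property
    def annotation_ids(self):
        return list(self._ids)


def index_add(index: RetrievalIndex, descriptor: CropDescriptor) -> RetrievalIndex:
    """Insert (or replace) one descriptor; O(1), no rebuild."""
    vec = np.asarray(descriptor.vector, dtype=np.float64)
    if vec.shape != (index.dimensionality,):
        raise ValidationError(
            f"descriptor dimension {vec.shape[0]} != index {index.dimensionality}")
    aid = descriptor.annotation_id
    if aid in index._row_of:
        index._vectors[index._row_of[aid]] = vec
    else:
        index._row_of[aid] = len(index._ids)
        index._ids.append(aid)
        index._vectors.append(vec)
    return index


def query_similar(index: RetrievalIndex, descriptor: CropDescriptor, k: int) -> list:
    """k nearest neighbours as ``[(annotation_id, distance), ...]`` ascending.

    Distance ties are broken by insertion order; an empty index returns an
    empty list.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if not index._ids:
        return []
    M = np.stack(index._vectors)
    q = np.asarray(descriptor.vector, dtype=np.float64)
    if q.shape != (index.dimensionality,):
        raise ValidationError("query dimension mismatch")
    dist = np.sqrt(((M - q) ** 2).sum(axis=1))
    order = np.argsort(dist, kind="stable")[:k]  # stable sort = insertion-order ties
    return [(index._ids[i], float(dist[i])) for i in order]


def suggest_terms(labels: dict, index: RetrievalIndex,
                  descriptor: CropDescriptor, k: int) -> list:
    """Rank ontology terms among the k nearest labeled neighbours.

    ``labels`` maps annotation_id -> term_id; unlabeled neighbours are
    skipped.  Returns ``[(term_id, support fraction), ...]`` by descending
    vote count, ties by smaller term id; support = votes / k.
    """
    votes: dict[int, int] = {}
    for aid, _ in query_similar(index, descriptor, k):
        if aid in labels:
            votes[labels[aid]] = votes.get(labels[aid], 0) + 1
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(tid, n / k) for tid, n in ranked]


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_index(index: RetrievalIndex, dirpath) -> None:
    os.makedirs(dirpath, exist_ok=True)
    with open(os.path.join(dirpath, "manifest.json"), "w") as fh:
        json.dump({"dimensionality": index.dimensionality,
                   "distance": index.distance,
                   "annotation_ids": index._ids}, fh)
    np.save(os.path.join(dirpath, "vectors.npy"),
            np.stack(index._vectors) if index._ids else
            np.empty((0, index.dimensionality)))


def load_index(dirpath) -> RetrievalIndex:
    with open(os.path.join(dirpath, "manifest.json")) as fh:
        m = json.load(fh)
    index = RetrievalIndex(m["dimensionality"], m["distance"])
    vectors = np.load(os.path.join(dirpath, "vectors.npy"))
    for aid, vec in zip(m["annotation_ids"], vectors):
        index_add(index, CropDescriptor(vector=vec, annotation_id=aid))
    return index


# ---------------------------------------------------------------------------
# Supervised object classification
# ---------------------------------------------------------------------------

@dataclass
class ObjectClassifier:
    ensemble: ExtraTreesClassifier
    resample: int
    classes: list = field(default_factory=list)


def train_object_classifier(crops, term_labels, n_trees=100, seed=0,
                            d: int = DEFAULT_RESAMPLE) -> ObjectClassifier:
    """Seeded tree ensemble over crop descriptors."""
    if n_trees <= 0:
        raise ValidationError("n_trees must be >= 1")
    labels = np.asarray(term_labels)
    if np.unique(labels).size < 2:
        raise ValidationError("need at least 2 classes")
    X = np.stack([extract_descriptor(c, d).vector for c in crops])
    est = ExtraTreesClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    est.fit(X, labels)
    return ObjectClassifier(ensemble=est, resample=d,
                            classes=[int(c) for c in est.classes_])


def classify_crop(model: ObjectClassifier, crop) -> tuple:
    """Predict (term_id, probability) for one crop; probability is the
    ensemble vote fraction of the winning term."""
    vec = extract_descriptor(crop, model.resample).vector
    proba = model.ensemble.predict_proba(vec[None, :])[0]
    i = int(np.argmax(proba))
    return model.classes[i], float(proba[i])
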