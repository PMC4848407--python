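"""Tiled multi-resolution pyramids over raster images.

A gigapixel image is stored as a stack of levels; level 0 is the full
resolution and each subsequent level halves both dimensions (ceil) until
the image fits in a single tile.  Tiles live on disk as PNG files under
``<root>/<plane>/<level>/<col>_<row>.png`` next to a ``manifest.json`` —
a greppable, diff-able layout.  Edge tiles are clipped, not padded, so the
level-0 mosaic reconstructs the source bit-exactly.

Planes of a 5D image (z, c, t) are independent 2D pyramids; there is no
volumetric fusion.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import shapely
import shapely.ops
import shapely.wkt
from PIL import Image
import tifffile

from .core_model import ValidationError

DEFAULT_TILE_SIZE = 256


class BoundsError(IndexError):
    """A tile address or region lies outside the pyramid extent."""


# ---------------------------------------------------------------------------
# Geometry of the level stack
# ---------------------------------------------------------------------------

def plan_levels(width: int, height: int, tile_size: int = DEFAULT_TILE_SIZE) -> list:
    """Level dimensions [(w, h), ...] by repeated ceil-halving.

    The stack stops at the first level whose larger dimension fits in one
    tile; there is always at least one level.
    """
    if width < 1 or height < 1:
        raise ValidationError("zero-sized image")
    dims = [(width, height)]
    while max(dims[-1]) > tile_size:
        w, h = dims[-1]
        dims.append((math.ceil(w / 2), math.ceil(h / 2)))
    return dims


def _plane_key(plane) -> str:
    z, c, t = plane
    return f"z{z}_c{c}_t{t}"


@dataclass
class TilePyramid:
    image_id: int
    tile_size: int
    n_levels: int
    level_dims: list
    storage_root: str | None = None  # None: metadata-only plan
    planes: list = field(default_factory=lambda: [(0, 0, 0)])
    reducer: str = "mean"

    @property
    def width(self) -> int:
        return self.level_dims[0][0]

    @property
    def height(self) -> int:
        return self.level_dims[0][1]

    def grid_shape(self, level: int):
        """(n_cols, n_rows) of the tile grid at a level."""
        w, h = self.level_dims[level]
        return (math.ceil(w / self.tile_size), math.ceil(h / self.tile_size))


@dataclass
class TileAddress:
    level: int
    col: int
    row: int


@dataclass
class RegionSpec:
    level: int
    x: int
    y: int
    width: int
    height: int
    plane: tuple = (0, 0, 0)


@dataclass
class CropResult:
    pixels: np.ndarray
    out_of_extent: np.ndarray  # bool mask, True where filled with background

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.pixels, dtype=dtype)


def plan_pyramid(width: int, height: int, tile_size: int = DEFAULT_TILE_SIZE,
                 image_id: int = 0) -> TilePyramid:
    """Metadata-only pyramid: level arithmetic without any pixel data."""
    dims = plan_levels(width, height, tile_size)
    return TilePyramid(image_id=image_id, tile_size=tile_size,
                       n_levels=len(dims), level_dims=dims, storage_root=None)


# ---------------------------------------------------------------------------
# Reduction
# ---------------------------------------------------------------------------

def reduce_2x(arr: np.ndarray, reducer: str = "mean") -> np.ndarray:
    """One 2x reduction step; output dims are the ceil-half of the input.

    ``mean`` averages 2x2 blocks (edge rows/columns replicated to even
    size); ``subsample`` keeps every other pixel and is bit-exact.
    """
    if reducer == "subsample":
        return arr[::2, ::2].copy()
    if reducer != "mean":
        raise ValueError(f"unknown reducer {reducer!r}")
    h, w = arr.shape[:2]
    ph, pw = h % 2, w % 2
    if ph or pw:
        pad = [(0, ph), (0, pw)] + [(0, 0)] * (arr.ndim - 2)
        arr = np.pad(arr, pad, mode="edge")
    a = arr.astype(np.float64)
    out = (a[0::2, 0::2] + a[0::2, 1::2] + a[1::2, 0::2] + a[1::2, 1::2]) / 4.0
    if np.issubdtype(arr.dtype, np.integer):
        out = np.rint(out)
    return out.astype(arr.dtype)


# ---------------------------------------------------------------------------
# Building
# ---------------------------------------------------------------------------

def _load_planes(image) -> dict:
    """Normalize the accepted source forms to {(z, c, t): 2D/3D array}."""
    if isinstance(image, dict):
        return {tuple(k): np.asarray(v) for k, v in image.items()}
    if isinstance(image, np.ndarray):
        return {(0, 0, 0): image}
    path = os.fspath(image)
    if not os.path.exists(path):
        raise IOError(f"unreadable source {path!r}")
    if path.lower().endswith((".tif", ".tiff")):
        pages = tifffile.imread(path)
        if pages.ndim == 2 or (pages.ndim == 3 and pages.shape[-1] in (3, 4)):
            return {(0, 0, 0): pages}
        return {(z, 0, 0): pages[z] for z in range(pages.shape[0])}
    return {(0, 0, 0): np.asarray(Image.open(path))}


def _write_tiles(arr: np.ndarray, level_dir: str, tile_size: int) -> None:
    os.makedirs(level_dir, exist_ok=True)
    h, w = arr.shape[:2]
    for row in range(math.ceil(h / tile_size)):
        for col in range(math.ceil(w / tile_size)):
            tile = arr[row * tile_size:(row + 1) * tile_size,
                       col * tile_size:(col + 1) * tile_size]
            Image.fromarray(tile).save(
                os.path.join(level_dir, f"{col}_{row}.png"))


def build_pyramid(image, storage_root, tile_size: int = DEFAULT_TILE_SIZE,
                  reducer: str = "mean", image_id: int = 0) -> TilePyramid:
    """Convert a raster source to an on-disk tile pyramid.

    ``image`` may be a 2D/3D numpy array, a PNG/TIFF path (multi-page TIFF
    pages become z planes) or a ``{(z, c, t): array}`` mapping.
    """
    if tile_size < 64:
        raise ValidationError("tile_size must be >= 64")
    planes = _load_planes(image)
    shapes = {a.shape[:2] for a in planes.values()}
    if len(shapes) != 1:
        raise ValidationError("all planes must share the same 2D shape")
    h, w = shapes.pop()
    dims = plan_levels(w, h, tile_size)
    pyr = TilePyramid(image_id=image_id, tile_size=tile_size, n_levels=len(dims),
                      level_dims=dims, storage_root=os.fspath(storage_root),
                      planes=sorted(planes), reducer=reducer)
    for plane, arr in planes.items():
        level_arr = arr
        for level in range(len(dims)):
            if level > 0:
                level_arr = reduce_2x(level_arr, reducer)
            assert level_arr.shape[:2] == (dims[level][1], dims[level][0])
            _write_tiles(level_arr, os.path.join(
                pyr.storage_root, _plane_key(plane), str(level)), tile_size)
    manifest = {
        "image_id": image_id, "tile_size": tile_size, "reducer": reducer,
        "n_levels": pyr.n_levels, "level_dims": [list(d) for d in dims],
        "planes": [list(p) for p in sorted(planes)],
    }
    with open(os.path.join(pyr.storage_root, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return pyr


def open_pyramid(storage_root) -> TilePyramid:
    """Open an on-disk pyramid from its manifest."""
    with open(os.path.join(os.fspath(storage_root), "manifest.json")) as fh:
        m = json.load(fh)
    return TilePyramid(
        image_id=m["image_id"], tile_size=m["tile_size"], n_levels=m["n_levels"],
        level_dims=[tuple(d) for d in m["level_dims"]],
        storage_root=os.fspath(storage_root),
        planes=[tuple(p) for p in m["planes"]], reducer=m["reducer"])


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _check_backed(pyr: TilePyramid) -> None:
    if pyr.storage_root is None:
        raise ValidationError("metadata-only pyramid has no pixel data")


def get_tile(pyr: TilePyramid, addr: TileAddress, plane=(0, 0, 0)) -> np.ndarray:
    """Read one tile; edge tiles are smaller than tile_size (clipped)."""
    _check_backed(pyr)
    if not (0 <= addr.level < pyr.n_levels):
        raise BoundsError(f"level {addr.level} out of range")
    n_cols, n_rows = pyr.grid_shape(addr.level)
    if not (0 <= addr.col < n_cols and 0 <= addr.row < n_rows):
        raise BoundsError(f"tile ({addr.col},{addr.row}) outside {n_cols}x{n_rows} grid")
    path = os.path.join(pyr.storage_root, _plane_key(plane), str(addr.level),
                        f"{addr.col}_{addr.row}.png")
    return np.asarray(Image.open(path))


def get_crop(pyr: TilePyramid, region: RegionSpec) -> CropResult:
    """Assemble an arbitrary rectangle at any level from the minimal tile set.

    Parts of the requested rectangle outside the level extent are filled
    with 0 and flagged in ``out_of_extent``.
    """
    _check_backed(pyr)
    if not (0 <= region.level < pyr.n_levels):
        raise BoundsError(f"level {region.level} out of range")
    if region.width < 1 or region.height < 1:
        raise ValidationError("region must be at least 1x1")
    lw, lh = pyr.level_dims[region.level]
    x0, y0 = region.x, region.y
    x1, y1 = x0 + region.width, y0 + region.height
    if x1 <= 0 or y1 <= 0 or x0 >= lw or y0 >= lh:
        raise BoundsError("region lies fully outside the level extent")
    ts = pyr.tile_size
    # probe one tile for dtype / band count
    probe = get_tile(pyr, TileAddress(region.level, 0, 0), region.plane)
    shape = (region.height, region.width) + probe.shape[2:]
    out = np.zeros(shape, dtype=probe.dtype)
    oob = np.ones((region.height, region.width), dtype=bool)
    cx0, cy0 = max(x0, 0), max(y0, 0)
    cx1, cy1 = min(x1, lw), min(y1, lh)
    for row in range(cy0 // ts, (cy1 - 1) // ts + 1):
        for col in range(cx0 // ts, (cx1 - 1) // ts + 1):
            tile = get_tile(pyr, TileAddress(region.level, col, row), region.plane)
            tx, ty = col * ts, row * ts
            sx0, sy0 = max(cx0, tx), max(cy0, ty)
            sx1 = min(cx1, tx + tile.shape[1])
            sy1 = min(cy1, ty + tile.shape[0])
            out[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = \
                tile[sy0 - ty:sy1 - ty, sx0 - tx:sx1 - tx]
            oob[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = False
    return CropResult(pixels=out, out_of_extent=oob)


def get_level_image(pyr: TilePyramid, level: int, plane=(0, 0, 0)) -> np.ndarray:
    """Full extent of one level (desk-scale convenience)."""
    w, h = pyr.level_dims[level]
    return get_crop(pyr, RegionSpec(level, 0, 0, w, h, plane)).pixels


# ---------------------------------------------------------------------------
# Coordinate mapping and mask rendering
# ---------------------------------------------------------------------------

def map_coordinates(wkt: str, from_level: int, to_level: int) -> str:
    """Rescale a geometry between pyramid levels (factor 2^(from-to))."""
    factor = 2.0 ** (from_level - to_level)
    geom = shapely.wkt.loads(wkt)
    return shapely.ops.transform(
        lambda x, y: (x * factor, y * factor), geom).wkt


def render_annotation_mask(image_dims, annotations, region: RegionSpec,
                           mode: str = "binary", known_terms=None) -> np.ndarray:
    """Rasterize annotations over a region at any pyramid level.

    A pixel is set iff its *center* lies inside or on the boundary of a
    geometry (level-0 geometries are scaled to the region's level).  In
    ``by-term`` mode the pixel value is the annotation's term id and later
    annotations (ascending id order) overwrite earlier ones on overlap;
    ``binary`` mode writes 1.

    ``annotations`` may be Annotation objects or ``(geometry, term_id)``
    pairs (term_id ignored in binary mode; plain geometries accepted then).
    """
    if mode not in ("binary", "by-term"):
        raise ValueError(f"unknown mode {mode!r}")
    h, w = region.height, region.width
    dtype = np.uint8 if mode == "binary" else np.int64
    mask = np.zeros((h, w), dtype=dtype)
    scale = 2.0 ** (-region.level)

    items = []
    for ann in annotations:
        if hasattr(ann, "shape") and hasattr(ann, "term_ids"):
            geom = ann.shape()
            tid = max(ann.term_ids) if ann.term_ids else None
            order = ann.id
        elif isinstance(ann, (tuple, list)):
            geom, tid = shapely.wkt.loads(ann[0]) if isinstance(ann[0], str) else ann[0], ann[1]
            order = len(items)
        else:
            geom = shapely.wkt.loads(ann) if isinstance(ann, str) else ann
            tid, order = None, len(items)
        items.append((order, geom, tid))
    items.sort(key=lambda it: it[0])

    xs = region.x + np.arange(w) + 0.5
    ys = region.y + np.arange(h) + 0.5
    for _, geom, tid in items:
        if mode == "by-term":
            if tid is None or (known_terms is not None and tid not in known_terms):
                raise ValidationError(f"unknown term {tid!r} in by-term mode")
        g = shapely.ops.transform(lambda x, y: (x * scale, y * scale), geom) \
            if region.level else geom
        minx, miny, maxx, maxy = g.bounds
        j0 = int(np.searchsorted(xs, minx))
        j1 = int(np.searchsorted(xs, maxx, side="right"))
        i0 = int(np.searchsorted(ys, miny))
        i1 = int(np.searchsorted(ys, maxy, side="right"))
        if j0 >= j1 or i0 >= i1:
            continue
        px, py = np.meshgrid(xs[j0:j1], ys[i0:i1])
        pts = shapely.points(px.ravel(), py.ravel())
        shapely.prepare(g)
        inside = shapely.intersects(g, pts).reshape(i1 - i0, j1 - j0)
        sub = mask[i0:i1, j0:j1]
        sub[inside] = 1 if mode == "binary" else tid
    return mask
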