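# Methods

This note documents the models, conventions and numerical choices behind
`gigaslice`, and what the synthetic test scenes do and do not establish
about behaviour on real data.

## Coordinate and geometry conventions

Pixel coordinates are 0-based with the origin at the top-left and y
increasing downward; pixel extents are half-open `[0, width) × [0, height)`.
Deployed slide viewers sometimes place the origin at the bottom-left, so
`core_model.flip_y` converts geometries between the two frames; nothing
else in the package depends on the choice.

Geometries are stored as WKT (Point, Polygon, MultiPolygon) and exchanged
as GeoJSON. Invalid polygons are repaired once, at ingestion, by zero-buffer
cleaning (falling back to `make_valid`), and the repair is logged; an
annotation that remains empty or zero-area after repair is rejected.
Manual edits (`edit_vertex`) are the opposite: an edit that would create an
invalid ring is *refused*, never silently repaired, because proofreading
requires predictable outcomes.

Mask rasterization uses the pixel-center rule: a pixel is foreground iff
its center lies inside or on the boundary of the (level-scaled) geometry.
This makes mask area converge to polygon area (the 500-px disc agrees
within 2%) and gives an exact correspondence for integer-aligned
rectangles. ROI counting uses a closed boundary: a point on the ROI edge
counts. Both conventions are deliberate, documented choices — spot markers
drawn on a region's edge must not vanish from its count.

Per-term area statistics union all same-term geometries before measuring,
so a region drawn twice contributes once and ratios against a reference
region cannot exceed 1 through double-drawing. Areas are always reported in
px²; µm² only when the image carries a resolution (µm/px), as
`px² × resolution²`.

## Entity model

The store enforces referential integrity at insertion time (unknown terms,
layers, images or planes are rejected), assigns monotonically increasing
integer ids and never reuses them. Serialization is a JSON document per
entity with a `type` discriminator; `parse(serialize(e)) == e` holds for
every entity type and is property-tested on randomized entities.

The blinded projection replaces image names/paths by `image-<id>` and layer
agents by `observer-<ordinal>`, where ordinals rank the sorted agent ids of
the project — stable under insertion order, so repeated exports of a
blinded study are consistent. The projection needs the store to derive
those ordinals, hence the signature `apply_blinded_view(store, project,
entity)`. Geometry, terms and all quantification-relevant fields pass
through untouched.

## Pyramids

Level `L` has dimensions `(ceil(w/2^L), ceil(h/2^L))`; the stack ends at the
first level whose larger dimension fits in one tile (default 256 px), so a
19968×25088 slide has 8 levels and a 78×98 level-0 tile grid. Level 0 is
full resolution; increasing level means coarser. Edge tiles are clipped
rather than padded so concatenating level-0 tiles reproduces the source
bit-exactly — the invariant the tests pin. Two reducers exist: `mean`
(2×2 block average, edge rows/columns replicated to even size; the
anti-aliased default) and `subsample` (every other pixel; bit-exact against
direct decimation, used in oracle tests). Planes (z, c, t) of a 5D image
are independent 2D pyramids under `<root>/z{z}_c{c}_t{t}/<level>/<col>_<row>.png`
with a `manifest.json`; there is no volumetric fusion. Out-of-extent parts
of a requested crop are filled with 0 and flagged in a boolean mask rather
than raising, because prediction tiling routinely over-reads edges.

## Segmentation

The segmenter treats segmentation as pixel classification with multiple
outputs: the descriptor of a `w × w` subwindow is its raw intensities, and
the target is the label of *every* pixel in the window, so one
extremely-randomized-trees ensemble (`ExtraTreesClassifier`, multi-output)
predicts a full `w × w` label patch at once. Training subwindows are drawn
uniformly (seeded) from positions where the window overlaps annotated
geometry; per-pixel labels come from the by-term rasterized mask, with
unannotated pixels labeled background (class code 0). Explicit background
exemplars (a "non-tumor" term) are mapped to code 0: they guide the sampler
into background texture without becoming a foreground class — the
foreground probability is always `1 − P(background)`.

At prediction time subwindows sit on a stride grid plus edge-snapped
rows/columns so borders are covered; each pixel's confidence is the mean
over all covering windows (and trees) of the foreground vote, verified
against a naive per-window loop oracle to 1e-12. The confidence map is
thresholded at `p ≥ threshold`, 8-connected components are vectorized into
staircase polygons built from row-run rectangles — polygon area equals
pixel count exactly, no smoothing — small components (`min_area`, in pixels
at the prediction level) are dropped, holes optionally filled, and
coordinates mapped to level 0. The whole pipeline is deterministic given
(seed, model, scene).

Defaults (`window_size=24`, `n_subwindows=50000`, `n_trees=100`) are
library defaults for real use. The acceptance experiments run the
documented desk-scale configuration — window 16, 1500 subwindows, 25
trees, stride 8 on a 2048×2048 scene — which recovers all five islets with
Dice ≈ 0.997 in seconds; the criterion bound (Dice ≥ 0.85, exact component
count) leaves room for less separable textures.

## Retrieval, classification, landmarks

The crop descriptor is the crop resampled (bilinear) to `d × d` (default
32; 16 in tests) with each channel standardized to mean 0, sd 1 (sd clamped
at 1 when 0, so constant crops map to the zero vector). Retrieval is exact
incremental nearest-neighbour search under Euclidean distance; insertion
never rebuilds anything, ties break by insertion order (stable argsort),
and re-adding an annotation id replaces its vector. This is a transparent,
replaceable strategy — the contract is the incremental ranked retrieval and
majority-vote term suggestion, not the specific descriptor. Because the
descriptor is standardized, it is blind to flat intensity shifts; the test
gallery therefore uses structured textures (gratings of different
orientation and period, a checkerboard) rather than textures differing only
in mean.

Landmark models are binary patch classifiers (raw intensities, odd patch
size, default 33; 25 in the test configuration): positives are patches
centered within radius R (default 5) of the annotated landmark, negatives
seeded-uniform at distance ≥ `min_negative_distance`. Detection scans a
stride grid row-major and returns the argmax center, so probability ties
resolve to the smallest y then smallest x; detection is single-level and
single-hypothesis, matching the move-if-mispositioned proofreading gesture,
which produces a reviewed copy and preserves the original with a provenance
link.

## Review workflow

One review layer exists per image (reviewers are recorded per entity, not
per layer); reviewed annotations are novel entities carrying
`original_id` + `action` (`accepted` / `edited` / `added`), and originals
are never modified — conservation is checked by multiset snapshot equality
over (id, WKT bytes, terms). Decisions are explicit: deciding an annotation
twice is an error, `revoke_decision` reopens one before finalization, and a
finalized session refuses everything. Finalization quantifies the review
layer with the same `area_statistics`/`export_statistics` path used
everywhere else, and reviewed layers are directly usable as segmentation
training input (the refinement loop).

## Agreement statistics

Fleiss' kappa is computed from the object × category count table:
`P_i = Σ_j n_ij(n_ij−1) / (n(n−1))`, `p_j = Σ_i n_ij / (Nn)`,
`κ = (P̄ − Σ_j p_j²) / (1 − Σ_j p_j²)`. Objects rated by fewer than two
observers are excluded from all statistics; for κ, objects not sharing the
modal rater count are excluded (reported via the table), never imputed.
When all mass sits in one category `P̄_e = 1` and κ is 1 for perfect
agreement, an error otherwise. The implementation is cross-checked in tests
against an independent textbook evaluation and against
`statsmodels.stats.inter_rater.fleiss_kappa`; Cohen's kappa (two raters) is
cross-checked against scikit-learn. Percent agreement is the fraction of
multiply-rated objects with a unanimous row, and equals 1 exactly when the
disagreement list is empty.

## Synthetic scenes — what they show and what they do not

All test inputs come from seeded generators (bit-reproducible by
construction): tissue scenes are Gaussian-noise textures with distinct
means (foreground/background gap ≥ 4 sd; defaults 170 vs 80 at sd 10) and
non-overlapping polygonal islets whose exact outlines are the truth; spot
scenes place dark disks strictly inside ROIs with a margin of one spot
radius; landmark scenes stamp a cross marker at a jittered, recorded
position; observer labels flip the truth with a per-observer confusion
probability. Scene sizes stay at or below 2048×2048 so every pipeline runs
in seconds on one CPU.

Passing these tests establishes the *mechanics* — sampling, voting,
vectorization, level mapping, counting, bookkeeping — under conditions
where the recognition problem itself is easy. It does not establish
recognition performance on real histology, where stain variation, texture
overlap and annotation noise dominate; the generators deliberately avoid
emulating those. Degenerate inputs are defined explicitly: both-empty
polygon sets score Dice = IoU = 1, empty retrieval indexes return empty
result lists, zero-area references and single-class training sets are
errors.

## Known limitations

No vendor slide formats (PNG/TIFF only), no HTTP tile serving, no
concurrent multi-reviewer sessions or merge policy, no approximate
nearest-neighbour scaling, no shape-model regularization across landmarks,
no stain normalization or color deconvolution. The CLI covers the scripted
workflows; interactive proofreading UIs are out of scope.
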