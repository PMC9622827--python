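# Methods

`scifig` analyzes raster figures from scientific publications for three
kinds of image-integrity evidence: duplicated regions inside one figure
(copy-move), near-duplicate figures across a document set (ranking),
and the probable history of reuse across papers (provenance).  This
note describes the models and procedures as implemented, the parameters
that matter, what the synthetic phantoms do and do not emulate, and the
numerical choices made where the design was open.

## Copy-move detection

### Model

A copy-move manipulation pastes a region of a figure elsewhere within
the same figure, either to duplicate an object (e.g. a band in a blot)
or to hide one under cloned background.  Detection is dense-field:
every pixel p gets a feature vector describing the patch around it, and
a nearest-neighbor field f maps p to the most similar patch elsewhere
in the image under squared Euclidean feature distance, excluding
trivially close offsets (`min_offset_px`, default 16).  Cloned regions
reveal themselves as coherent areas where f is (locally affine and)
mutually consistent.

Two feature branches run in parallel and their masks are fused by
pixelwise union:

* **Zernike branch** — magnitudes of Zernike moments |Z_nm|,
  n ≤ 5, computed on the disc of radius 8 px around each pixel of the
  luma image (12 features).  The sampled kernels are mean-corrected
  over the disc so a constant patch responds only in Z_00; because the
  disc grid maps onto itself under 90° rotation and mirroring, the
  magnitudes are *exactly* invariant under those patch transforms (the
  suite verifies agreement with a direct-summation oracle at 1e-6).
  This branch catches rotated and mirrored duplications but is blind to
  content whose luma barely varies.
* **RGB branch** — the raw 8×8×3 intensity block around each pixel
  (192 features).  Sensitive to any intensity or chroma structure,
  including isoluminant color content, but not transform-invariant.

Each branch is implemented as: dense features → randomized NN-field
search → bidirectional validation → match-significance gate → dense
linear fitting and morphology.  The stages:

1. **NN-field search.**  A randomized scheme alternating propagation
   and shrinking random search.  Propagation offers each pixel its two
   causal neighbors' offsets both zero-order (copy the offset) and
   first-order (linear prediction of the target from two collinear
   neighbors).  The first-order predictor is essential for mirrored or
   rotated clones, whose offset field is affine but not constant: a
   mirror changes the column offset by −2 per column, so zero-order
   propagation always misses it.  Random search draws four global
   restarts per pixel per iteration plus one candidate per window scale,
   halving from the image extent down to 1 px.  Eight iterations by
   default; on small (≤ 48 px) fields oracle comparisons use sixteen,
   where the search lands within 5% of exhaustive-search cost on
   phantom imagery.  Offsets must land on valid feature pixels and be
   at least `min_offset_px` long.  Fully deterministic given the seed.
2. **Bidirectional validation.**  A pixel p with partner q = p + f(p)
   survives only if ‖f(q) + f(p)‖∞ ≤ `bidir_tol_px` (default 2): the
   match must hold from A to B *and* from B back to A.  This removes
   most accidental matches that arise in imagery with narrow intensity
   ranges and repeated shapes.
3. **Match-significance gate.**  Pixels whose match cost exceeds
   `cost_rel_thresh` (default 0.25) times the median matched cost of
   the field are dropped.  Rationale: a verbatim clone copies even the
   pixel noise, so its cost is essentially zero, while the best match
   between two *different* near-uniform regions still pays the noise
   floor — which the field-wide median estimates.  Without this gate,
   two featureless background regions can map onto each other with
   mutually consistent, locally constant offsets and sail through both
   the bidirectional and the affine-coherence tests.  The gate assumes
   clones are pasted losslessly; re-compressed or re-noised clones
   would need a larger threshold (config-exposed).
4. **Dense linear fitting and morphology.**  Offsets are median
   filtered over a 7 px window (on surviving pixels); each pixel's
   offsets are then compared to a local affine (planar) least-squares
   fit over the 15×15 neighborhood and dropped when the squared
   residual exceeds `dlf_error_thresh` (4 px²).  Connected regions
   under `min_region_px` (50) are removed, every surviving pixel's
   partner p + f(p) is marked (so source and destination are both
   reported — the pre-dilation mask is symmetric under the partner
   map), and the mask is dilated by a 3 px disc.

### Figure-level orchestration

A figure is first split into panels (below) and overlaid text is
erased, then every unordered panel pair — including each panel with
itself — is examined.  Cross-panel pairs are laid side by side on a
canvas separated by an invalid gutter of width 2×(patch radius), so a
patch never straddles two panels and the single-image machinery applies
unchanged; the minimum-offset constraint suppresses near-self matches
within a panel.  Pair masks are mapped back to figure coordinates and
OR-ed per branch; the final mask is the union of the two branch masks
(`fusion="and"` gives the intersection instead — union is the default
because the branches are designed to catch disjoint failure modes).

Support geometry bounds what any single branch can recover: features
exist only where the whole patch fits, so a branch's mask is eroded by
its patch radius at clone boundaries and dilation recovers only 3 px.
For a 40–48 px clone the Zernike branch alone therefore tops out near
F1 ≈ 0.77 even when it finds every matchable pixel; the fused detector
reaches ≈ 0.97 because the RGB branch's support margin is half as wide.

### Panel segmentation and text masking

Panels are found by a deterministic heuristic standing in for a learned
detector behind the same interface: foreground = pixels darker than the
background intensity read off the 0.98 luma quantile (light-background
figures; a flag inverts), closed over 3×3 gaps, connected components'
bounding boxes merged when closer than 4 px, boxes under 32 px a side
dropped.  On clean synthetic grids this recovers planted panel boxes to
within ±2 px per edge; on real figures a trained detector should be
substituted (any `segment_panels`-compatible callable).

Text is localized by a glyph heuristic: components of pixels deviating
from the image median by ≥ 120 intensity levels (8-connected), kept
when 4–32 px tall, at most 8:1 elongated, and *thin* — one 3×3 binary
erosion wipes them out.  The thinness test is what separates 1–2 px
lettering strokes from filled shapes such as blot bands or cell bodies,
which the detector must not erase.  Components are grouped into lines
by vertical overlap and horizontal gaps up to one glyph height.
Detected regions are filled with the image median (so erased areas do
not become alien uniform patches) before feature extraction, and
keypoints falling inside text boxes are additionally discarded in the
ranking and provenance stages.  An external OCR engine can replace the
heuristic through `register_ocr_backend`.

## Image ranking

Each figure is described by up to 500 keypoints from the image plus up
to 500 from its horizontally mirrored version — keypoint descriptors
are rotation- and scale-invariant but do not cope with mirroring, a
common form of figure reuse, so the mirrored view is indexed alongside.
Keypoints come from a pluggable detector (default: scikit-image SIFT,
re-scored by the determinant-of-Hessian response at the keypoint's
scale and kept top-N by response); descriptors are RootSIFT (L1
normalize, element-wise square root), making Euclidean distance emulate
the Hellinger kernel.  All descriptors of a case live in a flat, exact
L2 inverted-file index in which every entry back-references its source
figure.  A query retrieves the 8 nearest stored descriptors per query
descriptor — entries of the query's own figure are skipped without
consuming a slot — and each retrieval votes for its source figure;
figures sorted by votes (ties: ascending summed neighbor distance,
then id) truncated to 10 form the rank.  Search is exhaustive by
design: a case holds at most ~10⁶ descriptors, where exact search is
cheap and reproducible.

## Provenance graphs

Pairs of figures are matched with 2000-point mirror-augmented RootSIFT
description (text regions excluded), mutual-nearest-neighbor matching
with Lowe's ratio test (0.8), and affine RANSAC (tolerance 5 px, 1000
trials, seeded); the inlier count is the pair's similarity.  Counts
below `min_inliers` (8) are zeroed so isolated noise matches never
enter the forest.  Mirrored-view keypoint coordinates are mapped back
to the original frame before geometric verification, so a mirror is
just an affine map with negative determinant and needs no special
casing.  The symmetric count matrix is reduced by Kruskal's
maximum-spanning-forest algorithm (edges by descending weight, ties by
lexicographic id pair — hand-rolled union-find for deterministic
tie-breaking) and each chosen edge is oriented from the earlier
publication date to the later; a later-published figure can never
donate content to an earlier one.  Equal or missing dates orient by
ascending figure id, and undated figures are exempt from the
constraint.  The output is a forest-shaped DAG; isolated figures
remain as singleton nodes.

## Synthetic phantoms

The generator produces the study conditions every stage is tested
under, with full ground truth and bit-reproducibility from the seed:

* **Blot panels** — light background (230±10) with dark elliptical
  bands (core ≈ bg − 140..165) on a lane grid, Gaussian blur σ 1.5,
  additive noise σ 3.
* **Micrograph panels** — dark two-scale textured background (base 50,
  smooth components of σ 4/std 15 and σ 1.5/std 10) with bright
  non-overlapping cell blobs of radius 5–15 px and Poisson shot noise.
  The texture matters: perfectly flat backgrounds yield no keypoints
  and would make the ranking and provenance stages degenerate in a way
  real micrographs are not.
* **Color panels** — smooth chroma fields along luma-neutral color
  directions at near-constant luma: rich RGB structure invisible to the
  Zernike-on-luma branch.
* **Figures** — panels on a white canvas with 12 px gutters, optional
  near-black label strips.
* **Clones** — a source box pasted disjointly under none / mirror /
  rot90 / rot180; truth mask = source ∪ destination.
* **Reuse chains** — paper k+1 derives its figure from paper k's by
  cropping to 64–85% of the area, resizing 0.8–1.2×, shifting
  brightness ±10 and mirroring with probability ½, under strictly
  increasing dates 90 days apart.  The chain is linear
  (derived-of-derived) on a single dense root panel: with branching
  topologies, two figures derived from the same parent share its
  resampling blur and genuinely match each other better than their
  parent — a structural confusion of count-based spanning trees, not a
  bug, and the reason sibling-heavy truth graphs are hard for this
  method class.

What the phantoms do **not** emulate: JPEG artifacts, brightness/
contrast post-processing of clones, overlapping annotations, arrows and
plot axes, chart panels, scanned-page geometry, or the label diversity
of real figures.  Passing tests show the algorithms are implemented
correctly and behave as designed under controlled conditions; they do
not predict accuracy on real retracted-paper imagery, which is far
noisier (published work in this area reports much lower scores on real
data than any number printed here).

## Problem sizes and runtime choices

Tests and the acceptance script use panels of 96–160 px, figures of
~200–360 px, clones of 40–48 px, 20-figure retrieval benchmarks and
7-paper reuse chains.  These sizes keep every stage comfortably fast on
one CPU while leaving each algorithm's behavior fully observable; all
are parameters, not limits of the implementation.  The NN-field search
and the offset-field post-processing are JIT-compiled (numba), costing
a few seconds of one-time compilation per process.

## Degenerate inputs and tie-breaking

Empty-vs-empty metric comparisons score 1 (pristine figures evaluate
cleanly); a figure without detectable panels is analyzed whole; panels
smaller than the feature support are skipped with a logged warning and
empty masks; featureless queries return empty ranks; index ties break
by insertion order; rank ties by summed distance then id; Kruskal ties
by id pair; equal-date edges orient by id.  All randomness (NN-field
init and search, RANSAC) flows from explicit seeds, and identical
inputs with identical seeds reproduce every output bit-for-bit.
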