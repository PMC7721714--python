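# Methods

This document explains how each stage of the pipeline works and why it is
built the way it is. The package segments and quantifies cells in 3D
membrane-fluorescence stacks of early embryos; every stage is exercised
end-to-end on synthetic phantoms with exact ground truth, so every design
decision here is testable.

Conventions: volumes are `(z, y, x)` voxel arrays; physical positions are
`(x, y, z)` in micrometres; spacing is isotropic unless stated.

## 1. Synthetic embryo phantoms (`morphoseg.phantom`)

Real embryo stacks have no exact ground truth, so the pipeline is
developed against a generator whose outputs come with one.

An embryo is an axis-aligned ellipsoid of cells. Cell geometry is a
Voronoi partition of the ellipsoid interior around rejection-sampled
nucleus sites (minimum pairwise separation enforced, so no cell is
degenerate). Three label fields are produced:

- `voronoi` — every interior voxel assigned to its nearest nucleus;
- `membrane_mask` — a both-sided shell around each Voronoi boundary,
  sealed so that no two distinct cells touch even diagonally
  (26-connectivity watertightness); this matters because watershed floods
  leak through any diagonal gap;
- `truth_labels` — `voronoi` with membrane voxels zeroed (what a
  cytoplasmic marker would label);
- `full_partition` — the *compartment partition*: every voxel, membrane
  included, assigned to the compartment whose interior is nearest, i.e.
  each wall split down its mid-plane. This is the correct reference for a
  ridge-flooding watershed, which also splits walls at their crest, so
  segmentation accuracy against it is not artificially capped by wall
  thickness.

The rendered `membrane_image` applies the degradations that make real
stacks hard: anisotropic Gaussian blur (axial sigma ≥ lateral),
depth-dependent attenuation, orientation-dependent dimming of walls
parallel to the optical axis, and additive Gaussian noise. A separate
`nucleus_image` renders Gaussian blobs at the nucleus sites. A lineage
table records per-nucleus name, parent and position.

Two controlled perturbations support the identity logic below:
`inject_division_frame` replaces one nucleus by two anaphase daughters
flanking the old position inside the still-undivided compartment, and
`carve_cavity` inserts a sealed nucleus-free sphere (an extracellular
cavity) entirely inside one cell.

The generator's defaults are study conditions: they were fixed before the
evaluation invariants were written and are never adjusted to make a test
pass.

## 2. Distance-class targets (`morphoseg.distance`)

Directly classifying voxels as membrane/not-membrane throws away geometry
and is brittle where walls are dim. Instead the learning target is the
Euclidean distance to the nearest membrane voxel, truncated at a maximum
`d_max` and discretized into `K + 1` classes with *geometrically
shrinking* bin widths, so class resolution concentrates near the walls
where the segmentation is decided. Class 0 is the membrane itself; class
`K` is "deep interior". A reverse-truncated variant (distance measured
from the cap downward) is retained for comparison.

The per-class loss weights are inversely proportional to class frequency
in the training targets, clipped to a bounded ratio, so the thin membrane
class is not drowned out by the bulky interior classes.

Distance transforms use `scipy.ndimage.distance_transform_edt`; tests
verify it voxel-for-voxel against a brute-force pairwise oracle.

## 3. The distance-map network (`morphoseg.net`)

A small encoder–decoder ("DMapNet") maps a membrane stack to per-voxel
distance-class probabilities. It is written in plain NumPy with a
hand-rolled reverse-mode tape (`net/autodiff.py`) and Adam: at the scale
this package runs (desk-scale CPU training on phantoms), a framework
dependency would cost more than it buys, and the tape is itself tested by
comparing gradients against central finite differences.

The architecture is pseudo-3D: convolutions are 2D within slices, and
depth context enters through the channel dimension. Because border slices
lack context, the network *excludes* a fixed number of boundary slices
from its output: the default configuration maps a 24-slice input to a
16-slice output (8 slices excluded, 4 per side). Tiles overlap
accordingly at prediction time.

The loss is weighted cross-entropy with an additional *inter-class*
penalty: misclassifying class `i` as class `j` is weighted by
`exp(|i − j| · K / (K + 1))`, so a far miss (deep-interior predicted on a
membrane voxel) costs exponentially more than an off-by-one. Tests pin
the closed form on uniform predictions, the far-miss ordering, and the
one-hot minimum.

`tiny_config()` is a reduced configuration (16-slice depth, 64-pixel
tiles, 2 levels) used in examples and acceptance tests; training it for
30 epochs on five small phantoms strictly decreases the mean loss and
beats the majority-class baseline on a held-out phantom.

## 4. Graph-seeded grouped watershed (`morphoseg.watershed`)

Given a per-voxel distance map `D` (predicted classes or the exact
transform), segmentation proceeds:

1. **Relief.** `relief = max(D) − D`; cells are basins, membranes are
   ridges.
2. **Seeds.** Regional minima of the relief after h-minima suppression
   (`h` merges basins shallower than `h`, removing noise minima). Each
   minimum is one vertex of the seed graph.
3. **Edge weights.** For each pair of nearby minima, the weight is the
   line integral of the *membrane interior distance* — the EDT into the
   membrane mask, zero off-membrane — sampled every half voxel along the
   straight segment between the minima. The key property: the weight is
   exactly zero iff the segment crosses no membrane. Two edge kinds are
   distinguished: E1 (general pairs) and E2 (pairs of minima adjacent to
   the volume boundary, which belong to the exterior background).
4. **Clustering.** Minima are grouped by cutting heavy E1 edges and
   keeping light ones. The default rule, `"crossing"`, cuts any E1 edge
   whose weight exceeds a small epsilon — i.e. clusters are the
   connected components of "can reach each other without crossing a
   membrane". An Otsu rule (threshold the weight histogram) and an
   explicit numeric threshold are also provided; on well-separated weight
   distributions all three coincide. E2 edges are never cut, so all
   exterior minima merge into a single background cluster.
5. **Flooding.** One marker per cluster; the flood field is
   `relief + membrane_interior_distance`, so ridge crests sit mid-wall
   and the resulting regions match the compartment partition rather than
   stopping at the inner wall surface.

`segment_from_mask` derives `D` from a membrane mask by exact EDT;
`segment_from_map` accepts a predicted class map; both share the
downstream path, and a test pins their equivalence on the exact map.

A note on Otsu: the between-class variance over a 256-bin histogram is
*exactly constant* across empty-gap bins between two well-separated
modes (every threshold in the gap induces the same data split). The
returned threshold is therefore one arbitrary bin center on that
plateau; tests compare attained variance, not the tie-broken bin.

## 5. Cell identity (`morphoseg.identity`)

Regions are named by the nuclei they contain, using the lineage table at
the segmented time point:

- one nucleus → the region takes that nucleus's name;
- two nuclei that are *sisters at anaphase* (same parent, parent recorded
  as dividing) → the region is the not-yet-divided mother and takes the
  mother's name; the daughter pair is recorded as resolved;
- two unrelated nuclei → a segmentation merge; the region is flagged
  `lost` rather than guessed;
- no nucleus → the region is either the exterior background (touches the
  volume boundary) or an internal `CAVITY`.

A nucleus that lands on a membrane voxel of the label field is resolved
by 3×3×3 neighborhood majority before giving up. `lost_cell_ratio` and
`cell_lifespans` aggregate over time, with the anaphase frame counted for
the mother (a daughter's lifespan starts the frame after the mother's
last).

## 6. Morphology and contacts (`morphoseg.atlas`)

Per-cell measurements: volume (voxel count × voxel volume), surface area
(marching-cubes mesh area on a lightly pre-smoothed mask), and the
dimensionless irregularity `eta = sqrt(S) / cbrt(V)`. `eta` is scale-free
and minimized by the sphere at
`2^(1/3) · 3^(1/3) · pi^(1/6) ≈ 2.1991`; a digitized ball of radius 20
voxels reproduces it within 0.2%. Caveat: for *very* small regions (a few
voxels across) the pre-mesh smoothing shrinks the measured surface
relative to the voxel-count volume, and measured `eta` can fall below
the sphere minimum; `eta` is meaningful for cell-sized regions only.

Contact areas count face-adjacent voxel pairs with distinct labels,
optionally bridging a one-voxel watershed ridge. The *effective contact*
filter discards spurious touches using a minimum relative area derived
from close packing: in a hexagonal close packing (kissing number 12) a
sphere shares its surface among 12 neighbors, and a further conservative
factor of 1/4 gives the default minimum contact fraction of 1/48; a
minimum duration in consecutive frames and a reproducibility quorum
across embryos complete the criteria.

`volume_inconsistency` scores a cell's volume trace against its
lifespan-wide median; `fit_powerlaw` fits `T = a · V^b` by ordinary
least squares in log–log space (cell-cycle length vs volume);
`sister_ratio_stats` summarizes volume asymmetry between sister cells.

## 7. Spatial standardization (`morphoseg.standardize`)

To compare per-cell positions across embryos imaged in arbitrary poses:

1. `symmetrize_z` — rotate the slice-stacking direction onto +y and
   center the stack on the xz plane;
2. `fit_min_ellipse_xz` — center the xz projection and rotate the major
   axis of its minimum-area enclosing ellipse (Khachiyan's algorithm)
   onto x;
3. `rescale_to_average` — per-axis rescale of each embryo to the cohort
   mean extent;
4. `normalize_positions` — refine each embryo onto a reference by
   interleaved *closed-form* single-family minimizers (Kabsch rotation,
   mean translation, per-axis positive scaling) of the summed squared
   same-cell distance. Each step is the exact minimizer with the other
   families fixed, so the objective is monotonically non-increasing;
   convergence is linear, not quadratic.

Per-cell spread across standardized embryos is summarized as
`Delta_r = sqrt(mean_i ||r_i − r_mean||^2)` (RMSD). A `literal_formula`
variant that omits the square on the norm is kept for comparison.

## 8. Evaluation metrics (`morphoseg.metrics`)

Dice coefficient per matched cell; symmetric Hausdorff distance (surface
or full-region, in µm); `unify_labels` matches predicted to true labels
by maximum total overlap via the Hungarian assignment (greedy matching is
demonstrably suboptimal and a test constructs a case where it fails);
`f1_curve` reports detection F1 over an IoU-threshold sweep;
`object_scores` classifies per-object outcomes (correct, split, merged,
missed, spurious).

Every nontrivial metric has a brute-force oracle in `tests/oracles.py`
(pairwise EDT, max–min Hausdorff, pure-Python line integrals, exhaustive
permutation assignment, explicit Otsu variance sums), and the acceptance
suite runs ≥50 random instances of each.

## Verification philosophy

- Oracles are written before the implementations they check, against the
  definition, not the code.
- Ground truth is analytic wherever possible (sphere `eta`, plane EDT,
  packing fractions, closed-form losses), digital-exact otherwise
  (compartment partition).
- Study conditions (phantom defaults, thresholds, seeds) are fixed ahead
  of evaluation and never tuned toward a pass.
- Known honest limitations are documented rather than hidden: global-Otsu
  thresholding of the *rendered image* loses cells even without noise,
  because orientation dimming thins walls parallel to the optical axis —
  which is precisely why the distance-class network exists; tiny-region
  `eta` is biased low; Otsu thresholds are plateau-ambiguous.
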