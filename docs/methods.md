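# Methods

This note records the models, parameter choices and numerical decisions
behind `somalayer`, and what the synthetic benchmarks do and do not show.

## Coordinate and unit conventions

Coordinates are 0-based voxel units `(x, y, z)`; a volume is stored C-ordered
as `data[z, y, x]` (x fastest), one TIFF page per z plane.  Physical position
is `index × voxel_size_um`, default 1 µm/voxel, so voxel units and µm
coincide unless a different voxel size is supplied.  All areas are reported
in image-space µm² of the unfolded surface; no correction is applied for
tissue shrinkage during solvent clearing (cleared tissue shrinks ~25%
linearly, so in-vivo areas would be larger by ~1.8×) — the package reports
what the image shows and leaves shrinkage correction to the user.

## Localization

**Semantic deconvolution** (optional).  A multilayer perceptron maps a
13×13×13 intensity patch to an equally sized target in [0, 1] in which
somata appear as bright spheres on a dark background: 2197 inputs, sigmoid
hidden layers of 500 and 200 units, linear 2197-unit output.  Training is
mini-batch Adam on mean-squared error, deterministic given the seed; the
held-out MSE at initialisation and after training are both reported so a
training run can be sanity-checked.  Applied convolutionally with stride 4,
overlapping predictions are averaged per voxel and border voxels not covered
by a full patch are copied from the input.  The network is authored in numpy
because the training contract (initialisation MSE, epoch-exact control,
bitwise determinism) is part of the module's public behaviour.  Training
patches must present objects at *all* offsets within the patch (including
partially visible ones) — a net trained only on centered objects degrades
badly when slid across a volume.

**Foreground threshold.**  Two-level maximum-entropy (Kapur) split of the
intensity histogram: `(t1, t2)` maximise the summed Shannon entropies of the
three classes `[0,t1]`, `(t1,t2]`, `(t2,max]`.  Partitions keeping all three
classes populated are preferred over partitions with an empty class;
without that preference the objective is degenerate on quasi-delta
histograms and can place both thresholds above all modes.  Ties break to
the lexicographically smallest pair.  The foreground threshold is `t1`.
The search is exhaustive over the occupied bin range (O(B²) with prefix
sums), exact for both 8- and 16-bit histograms.

**Seeds.**  A voxel seeds the mean shift iff (1) it is a 26-neighbourhood
local maximum and (2) the mean intensity of the radius-`r` ball around it
(truncated at borders) is strictly above `t1`.  Equal-valued plateaus —
common in saturated soma cores — yield one seed each, the lexicographically
smallest `(x, y, z)` member, so output is deterministic.  A plateau seed can
therefore sit anywhere inside a flat-cored soma; the subsequent mean shift,
not the seed, provides the sub-voxel center.  `r` defaults to 6 voxels (the
expected soma radius); lowering it relaxes condition (2) only, so recall is
monotonically non-decreasing in shrinking `r`.

**Mean shift.**  Each seed repeatedly moves to the intensity-weighted
center of mass of foreground voxels (intensity > `t1`) within a spherical
kernel of radius `R` (default 6) until the displacement falls below
`conv_tol` = 0.1 voxel (≪ soma radius) or 100 iterations.  Seeds whose
kernel holds no foreground mass are dropped.  Converged modes closer than
`merge_radius` = R/2 are merged single-link at their mass-weighted mean —
the standard resolution for seeds of one basin.

**Tiling.**  Large volumes are processed in overlapping substacks (defaults
280×282×246, overlap 28 voxels ≥ two soma diameters; the overlap value is a
package choice).  The foreground threshold is recomputed per substack, which
adapts to slowly varying illumination.  A detection is kept by the tile
whose core region (tile minus half the overlap margin on interior faces)
contains it; cores partition the volume, and because the overlap exceeds a
soma diameter, the owning tile always sees the soma whole.  Residual
duplicates within `merge_radius` are resolved keeping the higher mass.  On
volumes that fit in one tile this reduces exactly to direct processing.

**Manifold filter.**  For each detection, the distance to the layer is
estimated as the residual of a locally weighted quadric fit through its 30
nearest other detections: the neighbourhood's SVD plane provides in-plane
coordinates and heights, a quadric in the plane coordinates is fit with
Gaussian weights (bandwidth = median neighbour distance from the query),
and the residual |observed − predicted height| is the manifold distance.
The fit is exact for planar layers and second-order accurate on curved
ones (≤1 µm error on a 100 µm-radius sphere cap).  Detections beyond the
threshold (15 µm in the benchmarks; the right value depends on layer
thickness and must be chosen per dataset) are discarded.  On synthetic
folded layers with 5% planted off-layer points at ≥30 µm this removes
≥95% of them at ≲0.1% true-cell loss.

## Clustering

Exact Euclidean k-nearest neighbours (kd-tree with an O(n²) fallback for
rows whose k-th neighbour distance is tied); distance ties break by smaller
point id, making the partition independent of input order.  Clusters are
connected components of the mutual-kNN graph with ≥2 members; degree-0
points are isolated.  Because raising k only adds edges, the isolated count
is non-increasing and the largest cluster non-decreasing in k — the sweep
k = 3, 5, 8 exposes how a contiguous layer coalesces into one component.
Approximate neighbour search is deliberately not offered: cluster counts
are the deliverable.

## Gap analysis

**Slicing.**  The cloud is cut into slabs of 2000 voxels with 120-voxel
overlap perpendicular to a chosen axis (half-open intervals, last one
closed), so every cell lies in at least one chart and cells in an overlap
lie in exactly two.  Charts whose neighbour graph is disconnected raise an
error naming the largest component rather than silently embedding garbage.

**Unfolding.**  Isomap with 10 neighbours, dense eigensolver and exact
Dijkstra shortest paths, followed by a local stress-majorization polish:
shortest paths through a kNN graph zig-zag between samples and overestimate
geodesics by a few percent, a bias that neither more samples nor the MDS
step removes.  Since 3D chords between nearby cells equal intrinsic
geodesics up to O((spacing/curvature radius)²) — the regime a cell layer
occupies — the Isomap layout is refined by Guttman-transform iterations
(default cap 1500, early-stopped when stationary) against all chords
shorter than 3× the median kNN edge length.  On a hex-packed half-cylinder
chart of radius 50 µm this reduces the median pairwise distance error from
~1.8% to ~0.06%; flat sheets embed to ~2·10⁻⁵ relative error.  The
embedding is centered, rotated to principal axes, and sign-fixed (positive
skew per axis, falling back to the first point's sign), so repeated runs
are identical.

**Triangulation and pruning.**  Delaunay on the (u, v) embedding (CCW
orientation, zero-area triangles dropped).  Concave chart outlines produce
huge sliver triangles along the boundary; these are removed by iterating
"delete every boundary triangle with perimeter > threshold" to a fixed
point, recomputing boundary status each round so interior triangles are
only removable once exposed.  The threshold defaults to 4× the median edge
length — scale-free across cell densities — and can be overridden with an
absolute length.  Pruning is idempotent and refuses to delete the entire
triangulation.

**Empty convex regions.**  From every surviving triangle a region grows
breadth-first: an adjacent candidate joins iff the merged triangle union
still has a single simple boundary cycle, contains no triangulation vertex
except on that cycle, and the cycle is convex within 1.0° of angular
tolerance (absorbing floating-point noise).  Frontier candidates are
examined in ascending triangle id, so growth is deterministic; the result
is a lower bound on the maximal empty convex polygon through that seed (on
jittered grids with a removed disc, n ≤ 60, the greedy area matches the
exhaustive optimum and always respects it as an upper bound).  Region area
is the sum of member-triangle areas.  The per-cell statistic is the maximum
grown area over the triangles incident to the cell — the "largest empty
convex polygon tangent to the cell", interpreting tangency as incidence.
When charts overlap, a cell contributes its maximum once (deduplicated by
id) to the pooled distribution.

**Log-normal fit.**  μ and σ are the mean and population (1/n) standard
deviation of log areas — the exact maximum-likelihood estimates.  99%
intervals: normal theory for μ, chi-square (n−1 df) for σ; a degenerate
all-equal sample yields σ = 0 with a [0, 0] interval.  At n = 10⁵ the fit
recovers simulation truth within three standard errors and matches a
grid-search likelihood maximiser to 4 decimals at n = 100.

## Synthetic generators

The layer generator places cells on a jittered hexagonal lattice (pitch
12 µm, jitter σ 1.5 µm by default — Purkinje-like spacing) on a
developable sinusoidally folded surface (amplitude 80 µm, wavelength
400 µm), arc-length parameterised so the (u, v) → 3D map is an exact
isometry; a non-zero jitter also makes triangulations generic.  The
hexagonal base (rather than Poisson scatter) keeps the no-gap null's empty
convex areas tightly bounded, so planted gaps are unambiguous.  Gaps are
discs emptied in intrinsic coordinates; false positives are extra points at
uniform (u, v) offset 30–60 µm along the surface normal (both signs).  The
volume generator plants spheres of radius 6 voxels with a soft 1-voxel
edge at ≥15-voxel separation on a flat background, plus optional
curvilinear filaments (neurite-like clutter) and Gaussian noise, clipped to
the dtype.

What the generators do *not* emulate: anisotropic PSFs, depth-dependent
attenuation, vasculature shadows, tissue cracks, and spatially varying cell
density.  Passing benchmarks therefore demonstrates correctness of the
geometry and statistics under the stated model, not robustness to every
imaging artifact; on real data the manifold-filter threshold, pruning
factor and Isomap neighbourhood deserve inspection against the images.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use 128³ volumes with 20 somata,
layers of roughly 300–600 µm extent (0.7–3k cells), charts of ~1.5k cells
for unfolding checks, 50 clouds of up to 500 points for the clustering
oracle, and n ≤ 60 instances for the exhaustive empty-convex-polygon
oracle — sizes chosen so every oracle is exact and the full battery runs in
minutes on one core.  Scaling to full-organ clouds (10⁵–10⁶ cells) is a
matter of tiling and slicing, which the pipeline already does per substack
and per chart.

## Known limitations

* Greedy region growth is a lower bound; a cell's statistic can
  under-estimate the true maximal empty polygon when convexity forces an
  early stop (observed shortfalls on planted discs are <25%).
* The mutual-kNN graph at k = 3 fragments even regular lattices along row
  boundaries; conclusions about "clusters" at small k describe the
  relation's granularity, not necessarily anatomy.
* Isomap requires each chart to be connected and roughly developable;
  strongly non-developable patches (bumps, saddles at the slice scale)
  distort areas and should be cut into smaller charts.
* The deconvolution MLP is a contrast enhancer trained per dataset; it is
  optional, and all geometric guarantees hold on raw volumes.
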