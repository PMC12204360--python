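# Methods

This note records the models, conventions and design choices behind
`dmskel`, at the level of detail a user needs to interpret its outputs and a
maintainer needs to change them safely.

## The density field and its filtration

The input likelihood image is a density ρ ≥ 0 sampled at pixel centres,
treated as a Morse function on the 1-skeleton of the 2D cubical complex
(pixels = vertices, 4-neighbour adjacencies = edges; 2-cells are never
needed because only 0-dimensional persistence and the saddle→maximum graph
are used).  Ridges of ρ are extracted from the **superlevel** filtration —
vertices enter in decreasing ρ — implemented directly rather than by
negation.  The value of an edge is the *minimum* of its endpoint values:
the merging edge between two peaks is then the lowest point of the ridge
connecting them, which is the saddle the construction wants.

Ties are resolved by the strict total order (value, −linear index): of two
equal-valued pixels the one with the smaller row-major index is treated as
higher.  This makes every output deterministic across runs and platforms.
When an edge merges two superlevel components, the component whose maximum
is lower in this order dies (elder rule), giving the persistence pair
(birth maximum, merging saddle edge).  Pairs whose birth and death values
coincide (possible only on plateaus) are reported nowhere but retained
internally so that gradient tunnelling (below) can pass through flat spots.

## Gradient, plateaus, and degenerate critical points

The discrete gradient is a parent pointer per pixel: the highest strictly
higher-valued 4-neighbour, ties to the smallest index.  Flat regions need
global care: a plateau that touches higher ground drains breadth-first
toward its exit pixels (queue and neighbours in index order), while a
*maximal* plateau — a flat local maximum — drains to a single sink at its
minimum linear index.  A purely local pointer rule would create a spurious
sink at the index minimum of every plateau, including non-maximal ones;
the global resolution guarantees exactly one sink per maximal plateau,
and ascent from any pixel terminates in at most one step per pixel.

A flat maximum is one degenerate critical point, not many.  When a maximum
is retained (essential, or paired with persistence ≥ δ), its entire
constant-value plateau — pixels and internal grid edges — is part of the
skeleton.  On generic (noisy) images plateaus are single pixels and this
term is invisible; on idealized constant-intensity ridges it is what makes
the skeleton the full ridge polyline rather than a single point, since a
noiseless constant ridge has *no* finite pair with positive persistence.

## Graph extraction with persistence-guided tunnelling

Given a persistence threshold δ and an optional intensity floor:

* merging saddle edges with persistence ≥ δ and edge value ≥ floor are
  retained;
* from each retained saddle, ascents are traced into *both* components the
  saddle merged.  The saddle edge (u, v) has a merge vertex v (its lower
  endpoint); the ascent from u enters one component, but v's own steepest
  ascent may also lead there, so the sweep records an *anchor* — the
  earlier neighbour through which v was attached to the other component —
  and the trace ascends from u, v and the anchor.  Without the anchor the
  two peaks a saddle separates are frequently not connected through it,
  and the skeleton disintegrates into short disconnected ridgelets;
* an ascent that terminates at a maximum whose pair has persistence < δ
  (a cancelled, i.e. noise, maximum) tunnels across that pair's death
  saddle and continues climbing on the far side.  This is the discrete
  analogue of persistence-guided cancellation: it is what lets one
  retained saddle trace an entire crest through the many small noise
  maxima that sit along a real axon, and hence what bridges signal gaps.

Each cancelled maximum is expanded at most once and each pixel's upward
path is walked at most once, so extraction is effectively linear in image
size after the O(n α(n)) union-find sweep.  Edge sets are nested in δ:
raising δ only removes structure.  Isolated nodes are dropped; every
reported node lies on an edge.

Recommended use follows the "run low, clean later" strategy: δ low
(default 0.02 on unit-normalized likelihoods) so that no true ridge is
lost, with false structure removed by the cleanup stages.  The floor
defaults to 0 and exists to stop pure-background ridge tracing when no
mask is used.

## Cleanup: mask, forests, haircut

* **Mask.**  The likelihood is binarized at the threshold maximizing
  between-class variance over a 256-bin histogram (Otsu); Morse graph
  nodes at mask-false pixels are removed with their edges.  A user mask
  image or no mask are also supported.
* **Maximum spanning forest.**  Axons are trees; each connected component
  is reduced to its maximum-weight spanning tree (Kruskal, deterministic
  tie order by edge index).  Edge weight is the mean of the endpoint
  densities — the spec of the weight is an open design point; the mean
  preserves high-likelihood ridges and is consistent with how the graph
  was built.
* **Haircut.**  Noise maxima near a real fragment produce short terminal
  spurs.  A branch-to-endpoint path with ≤ 10 edges (configurable) whose
  axial step directions change at most once is pruned; genuinely curvy or
  long terminal branches survive.  One pass over the input forest is made
  (iterating to a fixed point could eat real short branches).  "Direction
  change" means any inequality of consecutive unit steps.
* **Fragments.**  Branchpoints (degree > 2) and endpoints (degree 1) are
  critical points; each fragment is a maximal path between critical points
  whose interior has degree 2.  A component that is a pure cycle becomes
  one closed fragment anchored at its minimum-index node.  Every edge
  belongs to exactly one fragment.  Fragments are written as GeoJSON
  LineStrings with coordinates (x, y) = (col, row) × pixel size in μm and
  properties length_um / n_vertices / endpoint types; the planar-μm
  convention is stated in the document's `crs_note`.

## Densities and lengths

Rasterization assigns each unit segment's length to the pixel containing
its midpoint (midpoints on a border go to the lower pixel index), divided
by pixel area: areal density in μm/μm².  Total length is conserved to
floating-point accuracy by construction.  Dividing by the optical section
thickness gives a volumetric density in μm/μm³.  Note the units: areal
densities are reported per μm² internally even where display conventions
differ.

Optical thickness defaults encode the two supported modalities: 2.5 μm for
whole-slide fluorescence (PSF FWHM 1.5 μm plus 0.5 μm mean axonal
diameter) and 3 μm for serial two-photon (FWHM 2 μm + 0.5 μm).  No
stereological angular correction is applied — in-plane projected length
under-counts obliquely oriented axons, so all totals are lower bounds; a
scalar multiplier can be applied downstream if an orientation distribution
is assumed.

Between imaged sections, round(spacing/thickness) − 1 intermediate planes
are linearly interpolated (40 μm spacing / 2.5 μm slabs → 15 planes; the
50/3 case rounds 15.67 to 16).  For identical neighbouring slabs this
multiplies the per-gap integrated length by exactly spacing/thickness.
Linear interpolation is the simplest scheme consistent with that
multiplication-factor property.

Coordinate transforms into an atlas space are *applied*, never estimated:
a dense (2, rows, cols) displacement grid is interpolated (nearest or
linear) at fragment vertices; connectivity is untouched and lengths are
recomputed in the target space.  Vertices outside the grid raise.

Per-compartment totals integrate density × voxel volume over an integer
label volume (label 0 = background), reported in metres and log10 metres.

Single neurons (SWC, standard 7 columns, μm coordinates) are voxelized by
subdividing each parent–child segment into pieces no longer than a quarter
voxel and accruing each piece's length to its midpoint's voxel; cable
length is conserved exactly.

## The surprise index

With tracer density p and neuron density q normalized on a shared voxel
grid (default voxel 100 μm), S = Σ q log₂(q/p) bits, with 0·log(0/·) := 0.
Logarithms are base 2 throughout so the uniform-p limiting case is exactly
log₂ n bits.  If q occupies voxels where the *estimated* p is zero (single
neurons are traced in different brains), S is undefined rather than
infinite: the tracer density is first extended to those voxels by
inverse-distance-power weighted k-nearest-neighbour interpolation from the
positive-p voxels (defaults k = 6, the 3D face-neighbour count, and
power 1) and then renormalized to sum 1 — the renormalization is required
for p to remain a distribution and perturbs S only at the third decimal
for small fills.  Reports include a histogram of S and both Pearson and
Spearman correlations of S against log10 total length, since the intended
monotone association is scale-free.

## Evaluation

Predicted and ground-truth skeletons are binary pixel sets; matching is
greedy nearest-first one-to-one within Euclidean radius Dr (ties broken by
pixel index), so each ground-truth pixel contributes at most one true
positive — two parallel detected lines cannot both claim one annotated
line.  Greedy maximal matching is the documented algorithm; it is bounded
above by the optimal assignment and below by half of it, and the tests
compare it against an optimal-assignment oracle on small images.
Following the stated counting rules literally, unmatched predictions lying
exactly on a ground-truth pixel are not false positives, and unmatched
ground-truth pixels lying on a prediction are not false negatives.  IOU is
computed as TP/(TP+FP+FN).  Empirical radii from the source application:
Dr = 5 at 0.46 μm/px (whole-slide), Dr = 3 at 1 μm/px (two-photon).
Degenerate denominators yield 0 with a warning.

## The phantom generator

The phantom emulates tracer-labelled axon images: per tree, a correlated
random walk (unit steps, heading jitter uniform within ±0.25 rad,
Y-branching with probability 0.02/step at 0.6–1.2 rad) grown to a 300-step
budget on a 256×256 tile; 3 trees by default.  Centrelines are rasterized
**4-connected** — the same grid adjacency the Morse skeleton lives on, so
predicted and true skeletons have comparable pixel densities under
one-to-one matching.  Images are drawn at a per-branch intensity in
[0.75, 1]·peak, with 3-px gap stretches at 10% intensity (weak label, not
zero) occurring at rate 0.02/step, blurred by a σ = 1 px Gaussian
cross-section (amplitude-normalized so a straight centreline keeps its
drawn intensity; diagonal runs sit near 0.7×), plus zero-clipped Gaussian
background noise of σ = 0.05.  All stochasticity comes from one seeded
generator; outputs are bit-identical per seed.

What the phantom does *not* emulate: tissue autofluorescence structure,
vasculature and section artifacts, saturated injection cores, axon
crossings at shallow angles, multi-scale intensity inhomogeneity.  Passing
recovery tests on phantoms therefore demonstrates the geometric/topological
correctness of the pipeline (gap bridging, junction handling, density
bookkeeping), not robustness to every real-tissue artifact — on real data
those regions are masked or proofread.

Problem sizes used in the tests and the acceptance script — 256×256
phantoms, 8×8 oracle fields, 10–40-voxel densities — were chosen as the
smallest sizes at which each property is informative.

## Known limitations

* 2D only: lengths are projections onto the section plane and under-count
  oblique axons; a 3D extraction would replace the 2D step.
* Single-process persistence: whole-slide-scale images should be tiled by
  the caller (the optional CLI batch mode processes images whole).
* The greedy evaluation matching is not the optimal assignment (documented
  above).
* Dense, overlapping labelling (e.g. near injection sites) violates the
  one-ridge-per-axon premise and is out of scope.
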