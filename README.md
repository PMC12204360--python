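# dmskel

Skeletonization of tracer-labelled neuronal processes in 2D microscopy
images using persistence-guided discrete Morse theory, with biologically
meaningful summarization (volumetric axon length densities, per-compartment
cable lengths) and an information-theoretic "surprise" index comparing
single-neuron morphologies to tracer-injection projection patterns.

## Who this is for

Anterograde tracer injections label hundreds to thousands of neurons at
once; their axons appear in whole-brain fluorescent or two-photon images as
thin bright curvilinear fragments with signal gaps, junctions and noise.
Counting labelled voxels quantifies such data only loosely.  `dmskel`
instead extracts centreline skeletons of the labelled fragments and converts
them into *length* densities — a quantity that relates directly to the
underlying axons and composes with single-neuron reconstructions.

## The method

A likelihood image is read as a density (Morse) function ρ defined on the
vertices of a 2D cubical grid complex.  Axon centrelines are mountain ridges
of ρ; the skeleton is the **1-unstable manifold** — ascending gradient paths
connecting saddle points to local maxima, "connecting peaks through
saddles".  Because the construction is global, it traces fragments across
low-intensity gaps that defeat threshold-based thinning.

1. **Persistence pairing.**  0-dimensional persistent homology of the
   superlevel filtration of ρ pairs each local maximum *b* with the merging
   saddle edge *d* where its component is absorbed; persistence |ρ(b) − ρ(d)|
   scores the importance of the ridge.
2. **Graph extraction.**  Saddles with persistence ≥ δ are kept; ascending
   V-paths are traced from both sides of each kept saddle, tunnelling
   through cancelled (persistence < δ) maxima, yielding the Morse graph
   skeleton G.
3. **Cleanup.**  G is intersected with an Otsu likelihood mask, reduced to
   per-component maximum spanning trees (axons are trees), and pruned of
   short low-curvature terminal spurs (the "haircut").  The result is
   decomposed into skeletal fragments between branchpoints/endpoints and
   vectorized as GeoJSON LineStrings with recorded lengths.
4. **Summarization.**  Fragment lengths are rasterized into an areal density
   (μm/μm²), divided by the optical section thickness (2.5 μm for
   whole-slide fluorescence, 3 μm for serial two-photon) to a volumetric
   density (μm/μm³), linearly interpolated across the unimaged planes
   between sections (e.g. round(40/2.5) − 1 = 15 planes), and integrated
   over labelled compartments to total cable length in metres.
5. **Surprise.**  With tracer density p and a single neuron's normalized
   voxel length distribution q on a common grid, the surprise is the
   relative entropy S = Σᵢ qᵢ log₂(qᵢ/pᵢ) bits: 0 for a "typical" neuron
   (q = p), log₂ n for a point mass against a uniform p over n voxels, and
   at most −log₂ min p.  Voxels where q > 0 but the estimated p = 0 are
   filled by inverse-distance-weighted nearest-neighbour interpolation.

Skeletons are scored against ground truth with distance-tolerant matching:
a predicted pixel is a true positive when matched one-to-one to a ground
truth pixel within radius Dr (greedy nearest-first); precision, recall, F1
and IOU follow.

## Worked example

The built-in phantom generator produces tracer-like images (random axonal
trees with Gaussian cross-sections, intensity variation, 3 px gaps at 10%
intensity, background noise) together with exact ground truth:

```python
import numpy as np
from dmskel import PhantomSpec, generate_phantom, evaluate_skeleton
from dmskel.evaluation import baseline_threshold_thinning
from dmskel.pipeline import PipelineConfig, skeletonize_field

field, gt, gt_frags = generate_phantom(PhantomSpec(seed=0))
frags, counts = skeletonize_field(field, PipelineConfig())
print(f"{len(frags)} fragments, total length {frags.total_length_um:.1f} um "
      f"(ground truth: {gt_frags.total_length_um:.1f} um)")

pred = np.zeros(field.shape, dtype=bool)
for frag in frags:
    for r, c in frag.vertices:
        pred[int(round(r)), int(round(c))] = True
print("Morse pipeline:", {k: round(v, 3) for k, v in evaluate_skeleton(pred, gt, dr=3.0).items()})
print("threshold+thinning baseline f1:",
      round(evaluate_skeleton(baseline_threshold_thinning(field.values), gt, dr=3.0)["f1"], 3))
```

prints

```
14 fragments, total length 1104.0 um (ground truth: 898.0 um)
Morse pipeline: {'tp': 1104, 'fp': 5, 'fn': 33, 'precision': 0.995, 'recall': 0.971, 'f1': 0.983, 'iou': 0.967}
threshold+thinning baseline f1: 0.799
```

The recovered skeleton covers 97% of the ground-truth centreline pixels at
Dr = 3 with 0.5% false positives; the baseline breaks at every
sub-threshold gap.  (The detected *pixel path* length, 1104 μm, exceeds the
smooth polyline length 898 μm by the expected ℓ₁/ℓ₂ rasterization factor —
axial grid paths are longer than the smooth curves they trace.)

The same workflow is scriptable from a shell:

```bash
dmskel phantom --seed 0 --out-img img.tif --out-gt gt.png
dmskel skeletonize --input img.tif --delta 0.02 --pixel-size-um 1.0 --out out/
dmskel evaluate --pred pred.png --gt gt.png --dr 3
dmskel summarize --frags out/img.geojson --shape 256 256 \
    --spacing-um 40 --optical-thickness-um 2.5 --out density.tif
```

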