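"""Synthetic tracer-labelled axon phantoms with ground-truth skeletons.

Emulates the appearance of tracer-labelled axon fragments in 2D likelihood
images: thin bright curvilinear tree structures with Gaussian cross-sections,
per-segment intensity variation, stretches of weak label ("gaps"), and
background noise.  Trees are grown as correlated random walks with stochastic
Y-branching; the rasterized centrelines are the ground-truth skeleton, and
the walks themselves form ground-truth fragments with known lengths, so the
whole skeletonization pipeline can be validated end to end with no external
data.

All stochasticity comes from one seeded generator; identical specs produce
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .morse import DensityField
from .postprocess import Fragment, FragmentSet, polyline_length_um

__all__ = ["PhantomSpec", "generate_phantom"]


def _draw_line_4connected(a, b):
    """Pixels of the segment a->b as a 4-connected chain.

    Like Bresenham but with an extra pixel inserted at every diagonal step,
    so the rasterized centreline is a path in the cubical grid adjacency --
    the same graph the Morse skeleton lives on.
    """
    rr, cc = draw_line(int(a[0]), int(a[1]), int(b[0]), int(b[1]))
    out_r, out_c = [rr[0]], [cc[0]]
    for r, c in zip(rr[1:], cc[1:]):
        if r != out_r[-1] and c != out_c[-1]:  # diagonal step: go axial first
            out_r.append(r)
            out_c.append(out_c[-1])
        out_r.append(r)
        out_c.append(c)
    return np.array(out_r), np.array(out_c)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic axon image.

    Defaults describe a moderately noisy tile: three trees, unit step length,
    gentle tortuosity, 1 px Gaussian cross-section, occasional 3 px gaps at
    10% residual intensity, and clipped Gaussian background noise at 5% of
    the unit peak.
    """

    seed: int = 0
    shape: tuple[int, int] = (256, 256)
    n_trees: int = 3
    branch_prob: float = 0.02
    step_len_px: float = 1.0
    max_turn_rad: float = 0.25
    profile_sigma_px: float = 1.0
    gap_rate: float = 0.02
    gap_len_px: int = 3
    gap_floor: float = 0.1
    noise_sigma: float = 0.05
    peak: float = 1.0
    steps_per_tree: int = 300
    pixel_size_um: float = 1.0
    margin_frac: float = 0.08

    def __post_init__(self) -> None:
        if self.shape[0] < 64 or self.shape[1] < 64:
            raise ValueError("phantom shape must be at least 64x64")
        for name in ("branch_prob", "gap_rate", "gap_floor", "margin_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_trees < 0 or self.steps_per_tree < 1 or self.gap_len_px < 0:
            raise ValueError("degenerate phantom spec")
        if self.step_len_px <= 0 or self.peak <= 0 or self.noise_sigma < 0:
            raise ValueError("degenerate phantom spec")


def _grow_tree(rng: np.random.Generator, spec: PhantomSpec) -> list[np.ndarray]:
    """Correlated random walk with stochastic Y-branching.

    Returns one polyline (float (row, col) vertices) per branch; a branch's
    first vertex lies on its parent branch.
    """
    n_rows, n_cols = spec.shape
    mr, mc = spec.margin_frac * n_rows, spec.margin_frac * n_cols
    start = np.array(
        [rng.uniform(mr, n_rows - 1 - mr), rng.uniform(mc, n_cols - 1 - mc)]
    )
    theta0 = rng.uniform(0, 2 * np.pi)
    budget = spec.steps_per_tree
    active = [(start, theta0)]
    polylines: list[np.ndarray] = []
    while active and budget > 0:
        pos, theta = active.pop(0)
        points = [pos.copy()]
        while budget > 0:
            budget -= 1
            theta += rng.uniform(-spec.max_turn_rad, spec.max_turn_rad)
            nxt = pos + spec.step_len_px * np.array([np.sin(theta), np.cos(theta)])
            if not (0 <= nxt[0] <= n_rows - 1 and 0 <= nxt[1] <= n_cols - 1):
                break
            pos = nxt
            points.append(pos.copy())
            if rng.random() < spec.branch_prob:
                side = 1.0 if rng.random() < 0.5 else -1.0
                active.append((pos.copy(), theta + side * rng.uniform(0.6, 1.2)))
        if len(points) >= 2:
            polylines.append(np.array(points))
    return polylines


def generate_phantom(spec: PhantomSpec):
    """Generate (likelihood image, ground-truth skeleton, ground-truth fragments).

    The centreline image is drawn at a per-segment intensity in
    [0.75, 1.0] * peak, gap stretches are drawn at ``gap_floor * peak``
    (weak label, not zero), the result is blurred with the Gaussian
    cross-section profile (amplitude-normalized so a straight centreline
    stays at its drawn intensity), and clipped Gaussian background noise is
    added.
    """
    rng = np.random.default_rng(spec.seed)
    n_rows, n_cols = spec.shape
    intensity_img = np.zeros(spec.shape, dtype=np.float64)
    gt = np.zeros(spec.shape, dtype=bool)
    gt_fragments: list[Fragment] = []

    for _ in range(spec.n_trees):
        for poly in _grow_tree(rng, spec):
            seg_intensity = rng.uniform(0.75, 1.0) * spec.peak
            # mark gap stretches along the walk
            n_seg = len(poly) - 1
            gap_mask = np.zeros(n_seg, dtype=bool)
            i = 0
            while i < n_seg:
                if rng.random() < spec.gap_rate:
                    gap_mask[i : i + spec.gap_len_px] = True
                    i += spec.gap_len_px
                else:
                    i += 1
            ipoly = np.rint(poly).astype(int)
            for s in range(n_seg):
                rr, cc = _draw_line_4connected(ipoly[s], ipoly[s + 1])
                gt[rr, cc] = True
                value = (spec.gap_floor if gap_mask[s] else 1.0) * seg_intensity
                intensity_img[rr, cc] = np.maximum(intensity_img[rr, cc], value)
            gt_fragments.append(
                Fragment(
                    vertices=tuple(map(tuple, poly)),
                    length_um=polyline_length_um(poly, spec.pixel_size_um),
                    kind=("endpoint", "endpoint"),
                )
            )

    if spec.profile_sigma_px > 0:
        blurred = ndimage.gaussian_filter(intensity_img, spec.profile_sigma_px, mode="constant")
        # renormalize so a straight unit-intensity centreline keeps amplitude 1
        blurred *= spec.profile_sigma_px * np.sqrt(2.0 * np.pi)
        image = blurred
    else:
        image = intensity_img
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    image = np.clip(image, 0.0, None)

    field = DensityField(image, spec.pixel_size_um)
    frags = FragmentSet(fragments=gt_fragments, pixel_size_um=spec.pixel_size_um)
    return field, gt, frags
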