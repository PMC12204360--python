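"""Information-theoretic "surprise" of single neurons over tracer injections.

A tracer injection labels a population of neurons; its voxelized line density
p_i (normalized to sum 1) is the probability that a unit of labelled axon
length falls in voxel i.  A single reconstructed neuron j has its own
normalized density q_ij.  The surprise of neuron j is the relative entropy

    S_j = sum_i q_ij * log2(q_ij / p_i)    [bits]

i.e. the extra information its morphology carries beyond the population
projection pattern.  S = 0 iff the neuron is "typical" (q = p); the most
surprising neuron concentrates all of its length on the weakest projection
voxel k = argmin p, giving S_max = -log2(min_i p_i); for uniform p over n
voxels, S_max = log2(n).

Because single neurons are traced in different brains than the tracer, a
neuron may occupy voxels where the estimated tracer density is zero; the
tracer density is then extended to those voxels by inverse-distance-weighted
nearest-neighbour interpolation before computing S (see :func:`fill_support`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr, spearmanr

__all__ = [
    "ProjectionDensity",
    "SurpriseScore",
    "normalize_density",
    "surprise",
    "fill_support",
    "surprise_report",
]

DEFAULT_VOXEL_SIZE_UM = 100.0


@dataclass(frozen=True)
class ProjectionDensity:
    """Non-negative per-voxel density over a common voxel grid.

    When ``normalized`` is True the values sum to 1 (within 1e-9) and can be
    read as a probability distribution of axon length over voxels.
    """

    values: np.ndarray
    normalized: bool = False
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if np.any(values < 0):
            raise ValueError("projection density has negative values")
        if self.normalized and abs(values.sum() - 1.0) > 1e-9:
            raise ValueError("normalized density does not sum to 1 within 1e-9")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class SurpriseScore:
    neuron_id: str
    surprise_bits: float
    total_length_um: float = float("nan")
    n_support_filled: int = 0


def normalize_density(raw, voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM) -> ProjectionDensity:
    """Normalize raw per-voxel lengths to a distribution summing to 1."""
    raw = np.asarray(raw, dtype=np.float64)
    total = raw.sum()
    if not total > 0:
        raise ValueError("cannot normalize an all-zero density")
    return ProjectionDensity(raw / total, normalized=True, voxel_size_um=voxel_size_um)


def surprise(
    q: ProjectionDensity,
    p: ProjectionDensity,
    neuron_id: str = "",
    total_length_um: float = float("nan"),
    n_support_filled: int = 0,
) -> SurpriseScore:
    """Kullback-Leibler divergence S = sum q log2(q/p), in bits.

    Terms with q_i = 0 contribute 0 (by continuity).  If q is positive on a
    voxel where p is zero, S would be infinite; an explicit error directs the
    caller to :func:`fill_support` instead.
    """
    if not (q.normalized and p.normalized):
        raise ValueError("both densities must be normalized (see normalize_density)")
    if q.values.shape != p.values.shape:
        raise ValueError("q and p must live on the same voxel grid")
    qv = q.values.ravel()
    pv = p.values.ravel()
    support = qv > 0
    if np.any(pv[support] == 0):
        n_bad = int(np.sum(pv[support] == 0))
        raise ValueError(
            f"q is positive on {n_bad} voxel(s) where p is zero; "
            "interpolate p onto the union support with fill_support first"
        )
    s = float(np.sum(qv[support] * np.log2(qv[support] / pv[support])))
    # Gibbs' inequality guarantees S >= 0; clamp float round-off at q ~= p
    s = max(s, 0.0)
    return SurpriseScore(
        neuron_id=neuron_id,
        surprise_bits=s,
        total_length_um=total_length_um,
        n_support_filled=n_support_filled,
    )


def fill_support(
    p: ProjectionDensity,
    q_union_support: np.ndarray,
    k: int = 6,
    power: float = 1.0,
) -> tuple[ProjectionDensity, int]:
    """Extend a tracer density onto voxels occupied only by single neurons.

    Each voxel in ``q_union_support`` (boolean array, same grid as p) where p
    is zero receives the inverse-distance^power weighted mean of its k
    nearest positive-p voxels (distances between voxel centres); the result
    is renormalized to sum 1.  Previously positive voxels keep their relative
    proportions.  Returns (filled density, number of voxels filled).

    Defaults k=6 (3D face-neighbour heuristic) and power=1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = p.values.copy()
    pos = values > 0
    if not pos.any():
        raise ValueError("p has no positive voxels")
    support = np.asarray(q_union_support, dtype=bool)
    if support.shape != values.shape:
        raise ValueError("support mask must share p's grid shape")
    to_fill = support & ~pos
    n_fill = int(to_fill.sum())
    if n_fill:
        pos_coords = np.argwhere(pos).astype(np.float64)
        pos_values = values[pos]
        tree = cKDTree(pos_coords)
        fill_coords = np.argwhere(to_fill).astype(np.float64)
        kk = min(k, len(pos_coords))
        dist, idx = tree.query(fill_coords, k=kk)
        dist = np.atleast_2d(dist.reshape(len(fill_coords), kk))
        idx = np.atleast_2d(idx.reshape(len(fill_coords), kk))
        weights = 1.0 / dist**power  # targets have p == 0, so dist > 0
        filled = (weights * pos_values[idx]).sum(axis=1) / weights.sum(axis=1)
        values[to_fill] = filled
    total = values.sum()
    return (
        ProjectionDensity(values / total, normalized=True, voxel_size_um=p.voxel_size_um),
        n_fill,
    )


def surprise_report(scores, bins=10) -> dict:
    """Histogram of surprise indices and the length-surprise correlation.

    Returns a dict with histogram counts/edges, a per-neuron table, and the
    Pearson and Spearman correlations between log10 total length and S
    (reported as NaN with a warning when degenerate).
    """
    scores = list(scores)
    if not scores:
        raise ValueError("need at least one surprise score")
    s = np.array([sc.surprise_bits for sc in scores])
    lengths = np.array([sc.total_length_um for sc in scores])
    counts, edges = np.histogram(s, bins=bins)
    table = pd.DataFrame(
        {
            "neuron_id": [sc.neuron_id for sc in scores],
            "surprise_bits": s,
            "total_length_um": lengths,
            "n_support_filled": [sc.n_support_filled for sc in scores],
        }
    )
    pearson = spearman = float("nan")
    ok = np.isfinite(lengths) & (lengths > 0)
    if ok.sum() >= 2 and np.ptp(s[ok]) > 0 and np.ptp(lengths[ok]) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pearson = float(pearsonr(np.log10(lengths[ok]), s[ok]).statistic)
            spearman = float(spearmanr(np.log10(lengths[ok]), s[ok]).statistic)
    else:
        warnings.warn("length-surprise correlation undefined (constant or missing data)")
    return {
        "histogram_counts": counts,
        "histogram_edges": edges,
        "table": table,
        "pearson_log10length_vs_surprise": pearson,
        "spearman_log10length_vs_surprise": spearman,
    }
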