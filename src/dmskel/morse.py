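"""Persistence-guided discrete Morse graph extraction on 2D density fields.

The likelihood image is treated as a density (Morse) function rho defined on
the vertices of a 2D cubical grid complex (pixels are vertices, 4-neighbour
pixel adjacencies are edges).  Bright curvilinear structures appear as
mountain ridges of rho; the graph skeleton is the 1-unstable manifold: the
union of ascending gradient paths connecting merging saddle edges to local
maxima, i.e. the paths "connecting peaks through saddles".

Zero-dimensional persistent homology of the superlevel-set filtration of rho
(equivalently, the sublevel filtration of -rho) assigns each merging saddle an
importance score -- the persistence of the peak it kills -- which is used to
discard ridges created by noise.

Conventions, fixed here once and used everywhere:

* superlevel filtration: vertices enter in decreasing rho; the value of an
  edge is the *minimum* of its endpoint values (the lowest point of the ridge
  between two peaks);
* ties are broken by the strict total order (value, -linear_index): of two
  equal-valued pixels the one with the smaller linear (row-major) index is
  "higher"/older;
* elder rule: when an edge merges two superlevel components, the component
  whose maximum is lower in the total order dies.

Flat maxima (plateaus) are degenerate critical points; a plateau is treated
as a single critical entity and contributes all of its pixels and internal
grid edges to the graph when its maximum is retained.  On generic fields
plateaus are single pixels and this reduces to the plain V-path construction.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field as dataclass_field
from typing import Iterator

import numpy as np
from scipy import ndimage

__all__ = [
    "DensityField",
    "PersistencePair",
    "MorseGraph",
    "smooth_density",
    "compute_persistence_0d",
    "steepest_ascent_forest",
    "extract_morse_graph",
]

Pixel = tuple[int, int]
Edge = tuple[Pixel, Pixel]


@dataclass(frozen=True)
class DensityField:
    """A non-negative scalar field sampled at pixel centres.

    Parameters
    ----------
    values
        2D array of finite, non-negative reals (likelihood; dimensionless).
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    """

    values: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError(f"density field must be 2D, got shape {values.shape}")
        if values.shape[0] < 2 or values.shape[1] < 2:
            raise ValueError(f"density field needs >= 2 rows and columns, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("density field contains non-finite values")
        if np.any(values < 0):
            raise ValueError("density field contains negative values")
        if not (self.pixel_size_um > 0 and np.isfinite(self.pixel_size_um)):
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class PersistencePair:
    """A finite 0-dimensional persistence pair of the superlevel filtration.

    ``birth_vertex`` is the local maximum at which the dying superlevel
    component was born; ``death_edge`` is the merging saddle edge at which it
    was absorbed into an older component.
    """

    birth_vertex: Pixel
    death_edge: Edge
    birth_value: float
    death_value: float

    @property
    def persistence(self) -> float:
        return self.birth_value - self.death_value


@dataclass
class MorseGraph:
    """Geometric graph skeleton embedded on the pixel grid.

    Nodes are pixel (row, col) pairs; edges are axial grid edges.  ``maxima``
    are the retained critical maxima, ``saddle_edges`` the retained merging
    saddle edges.
    """

    shape: tuple[int, int]
    edges: set[Edge] = dataclass_field(default_factory=set)
    node_density: dict[Pixel, float] = dataclass_field(default_factory=dict)
    maxima: set[Pixel] = dataclass_field(default_factory=set)
    saddle_edges: set[Edge] = dataclass_field(default_factory=set)

    @property
    def nodes(self) -> set[Pixel]:
        out: set[Pixel] = set()
        for u, v in self.edges:
            out.add(u)
            out.add(v)
        return out

    def __len__(self) -> int:
        return len(self.edges)


def _canonical_edge(u: Pixel, v: Pixel) -> Edge:
    return (u, v) if u <= v else (v, u)


def smooth_density(field: DensityField, sigma: float) -> DensityField:
    """Gaussian-smooth a density field.

    Uses reflect boundary handling, which preserves constant fields and
    invents no values at the borders.  ``sigma`` is in pixels; ``sigma == 0``
    returns the input unchanged.
    """
    if not np.isfinite(sigma) or sigma < 0:
        raise ValueError(f"sigma must be a finite non-negative real, got {sigma}")
    if sigma == 0:
        return field
    smoothed = ndimage.gaussian_filter(field.values, sigma=sigma, mode="reflect")
    # tiny negative round-off can appear; clamp to keep the invariant
    np.clip(smoothed, 0.0, None, out=smoothed)
    return DensityField(smoothed, field.pixel_size_um)


def _neighbors(idx: int, n_rows: int, n_cols: int) -> Iterator[int]:
    """4-neighbour linear indices in ascending order."""
    r, c = divmod(idx, n_cols)
    if r > 0:
        yield idx - n_cols
    if c > 0:
        yield idx - 1
    if c < n_cols - 1:
        yield idx + 1
    if r < n_rows - 1:
        yield idx + n_cols


def _rank_order(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total order (value desc, linear index asc).

    Returns ``order`` (linear indices sorted from highest to lowest) and
    ``rank`` (inverse permutation: rank[v] = position of v in that order, so
    smaller rank means higher in the filtration).
    """
    flat = values.ravel()
    idx = np.arange(flat.size)
    order = np.lexsort((idx, -flat))
    rank = np.empty_like(order)
    rank[order] = idx
    return order, rank


class _UnionFind:
    __slots__ = ("parent", "root_max")

    def __init__(self, n: int) -> None:
        self.parent = np.full(n, -1, dtype=np.int64)  # -1: not yet added
        self.root_max = np.full(n, -1, dtype=np.int64)  # birth vertex of the component

    def add(self, v: int) -> None:
        self.parent[v] = v
        self.root_max[v] = v

    def find(self, v: int) -> int:
        root = v
        parent = self.parent
        while parent[root] != root:
            root = parent[root]
        while parent[v] != root:
            parent[v], v = root, parent[v]
        return root


def _persistence_sweep(field: DensityField):
    """Union-find sweep over the superlevel filtration.

    Returns (pairs, anchors, essential_maxima, rank).  ``pairs`` is the list
    of finite PersistencePairs (zero-persistence diagonal pairs dropped);
    ``anchors[i]`` is, for pair i with death edge (u, v) where v is the
    merging (lower) vertex, the earlier neighbour of v on the *other*
    component's side -- ascending from u reaches one merged component and
    ascending from the anchor reaches the other, which is what makes the
    traced graph connect the two peaks the saddle separates.
    ``essential_maxima`` holds the one unpaired maximum per grid-connected
    region.
    """
    values = field.values
    n_rows, n_cols = values.shape
    flat = values.ravel()
    order, rank = _rank_order(values)
    uf = _UnionFind(flat.size)
    pairs: list[PersistencePair] = []
    anchors: list[int] = []

    for v in order:
        uf.add(v)
        v_comp = uf.find(v)
        first_neighbor = -1
        for u in _neighbors(int(v), n_rows, n_cols):
            if uf.parent[u] == -1:
                continue
            if first_neighbor == -1:
                first_neighbor = u
            u_comp = uf.find(u)
            if u_comp == v_comp:
                continue
            # merging edge (u, v); edge value = min endpoint value = flat[v]
            max_u = uf.root_max[u_comp]
            max_v = uf.root_max[v_comp]
            # elder rule in the total order: lower maximum dies
            dying = max_u if rank[max_u] > rank[max_v] else max_v
            surviving_comp = v_comp if dying == max_u else u_comp
            dying_comp = u_comp if dying == max_u else v_comp
            uf.parent[dying_comp] = surviving_comp
            uf.root_max[surviving_comp] = max_u if dying == max_v else max_v
            v_comp = uf.find(v)
            birth_value = float(flat[dying])
            death_value = float(flat[v])
            # zero-persistence (diagonal) merges arise only on plateaus/ties;
            # they are kept for gradient tunneling but never reported
            pairs.append(
                PersistencePair(
                    birth_vertex=tuple(divmod(int(dying), n_cols)),
                    death_edge=_canonical_edge(
                        tuple(divmod(int(u), n_cols)), tuple(divmod(int(v), n_cols))
                    ),
                    birth_value=birth_value,
                    death_value=death_value,
                )
            )
            anchors.append(first_neighbor)

    roots = {uf.find(int(v)) for v in order}
    essential = [tuple(divmod(int(uf.root_max[r]), n_cols)) for r in roots]
    return pairs, anchors, essential, rank


def compute_persistence_0d(field: DensityField) -> list[PersistencePair]:
    """0-dimensional persistence pairs of the superlevel-set filtration.

    Components are born at local maxima of rho and die at the merging saddle
    edges where they are absorbed into an older (higher-peaked) component.
    Pairs are returned sorted by persistence descending (ties by birth pixel
    index ascending).  Exactly one maximum per grid-connected region is
    essential and is not reported as a pair.
    """
    pairs, _, _, _ = _persistence_sweep(field)
    n_cols = field.shape[1]
    pairs = [p for p in pairs if p.persistence > 0]
    pairs.sort(key=lambda p: (-p.persistence, p.birth_vertex[0] * n_cols + p.birth_vertex[1]))
    return pairs


def steepest_ascent_forest(field: DensityField) -> np.ndarray:
    """Discrete gradient: each pixel points toward its steepest ascent.

    A pixel with a strictly higher-valued 4-neighbour points to the highest
    of them (ties broken by smallest linear index).  Flat regions (plateaus)
    are resolved globally: a plateau that touches strictly higher ground
    drains deterministically toward those exit pixels (breadth-first, queue
    and neighbours ordered by linear index); a *maximal* plateau -- a flat
    local maximum -- drains to a single sink at its minimum linear index,
    which points to itself.  Following pointers from any vertex terminates at
    such a sink in at most (#pixels) steps.  Returns a flat ``parent`` array
    of linear indices.
    """
    values = field.values
    n_rows, n_cols = values.shape
    n = values.size
    flat = values.ravel()

    NEG = -np.inf
    nbr_val = np.full((4, n_rows, n_cols), NEG, dtype=np.float64)
    nbr_idx = np.zeros((4, n_rows, n_cols), dtype=np.int64)
    lin = np.arange(n, dtype=np.int64).reshape(n_rows, n_cols)
    # order: up, left, right, down -- ascending neighbour index, which makes
    # np.argmax's first-wins tie rule pick the smallest linear index
    nbr_val[0, 1:, :] = values[:-1, :]
    nbr_idx[0, 1:, :] = lin[:-1, :]
    nbr_val[1, :, 1:] = values[:, :-1]
    nbr_idx[1, :, 1:] = lin[:, :-1]
    nbr_val[2, :, :-1] = values[:, 1:]
    nbr_idx[2, :, :-1] = lin[:, 1:]
    nbr_val[3, :-1, :] = values[1:, :]
    nbr_idx[3, :-1, :] = lin[1:, :]

    higher = nbr_val > values[None, :, :]
    nbr_val = np.where(higher, nbr_val, NEG)
    best = np.argmax(nbr_val, axis=0)
    rows, cols = np.indices((n_rows, n_cols))
    parent = np.where(
        nbr_val[best, rows, cols] > NEG, nbr_idx[best, rows, cols], -1
    ).ravel()

    # resolve plateaus: connected equal-value regions of unresolved pixels
    unresolved = np.flatnonzero(parent == -1)
    seen = np.zeros(n, dtype=bool)
    for seed in unresolved:
        if seen[seed] or parent[seed] != -1:
            continue
        level = flat[seed]
        plateau = []
        queue = deque([int(seed)])
        seen[seed] = True
        while queue:
            v = queue.popleft()
            plateau.append(v)
            for u in _neighbors(v, n_rows, n_cols):
                if not seen[u] and flat[u] == level:
                    seen[u] = True
                    queue.append(u)
        exits = sorted(v for v in plateau if parent[v] != -1)
        if not exits:
            sink = min(plateau)
            parent[sink] = sink
            exits = [sink]
        queue = deque(exits)
        while queue:
            v = queue.popleft()
            for u in _neighbors(v, n_rows, n_cols):
                if flat[u] == level and parent[u] == -1:
                    parent[u] = v
                    queue.append(u)
    return parent


def _plateau(values: np.ndarray, start: int) -> list[int]:
    """Connected set of pixels with the same value as ``start`` (4-adjacency)."""
    n_rows, n_cols = values.shape
    flat = values.ravel()
    level = flat[start]
    seen = {start}
    queue = deque([start])
    while queue:
        v = queue.popleft()
        for u in _neighbors(v, n_rows, n_cols):
            if u not in seen and flat[u] == level:
                seen.add(u)
                queue.append(u)
    return sorted(seen)


def extract_morse_graph(field: DensityField, delta: float, floor: float = 0.0) -> MorseGraph:
    """Persistence-simplified discrete Morse graph skeleton.

    Retains every merging saddle edge whose persistence is >= ``delta`` and
    whose edge value is >= ``floor``, together with the ascending V-paths from
    both of its endpoints to their maxima (following
    :func:`steepest_ascent_forest`).  Maxima that are essential or that belong
    to a retained pair contribute their full constant-value plateau (flat
    maxima are single critical entities; on generic fields the plateau is one
    pixel).  Isolated nodes are dropped.

    Parameters
    ----------
    delta
        Persistence threshold; ridges whose importance is below it are
        considered noise.  Must be >= 0.
    floor
        Minimum saddle edge value; avoids tracing pure-background ridges in
        unmasked use.  Default 0 (no floor).
    """
    if not np.isfinite(delta) or delta < 0:
        raise ValueError(f"delta must be a finite non-negative real, got {delta}")
    if floor < 0:
        raise ValueError(f"floor must be >= 0, got {floor}")

    values = field.values
    n_rows, n_cols = values.shape
    flat = values.ravel()
    pairs, anchors, essential, _ = _persistence_sweep(field)
    parent = steepest_ascent_forest(field)

    def lin(p: Pixel) -> int:
        return p[0] * n_cols + p[1]

    def pix(i: int) -> Pixel:
        return tuple(divmod(i, n_cols))

    graph = MorseGraph(shape=(n_rows, n_cols))

    def add_edge(a: int, b: int) -> None:
        graph.edges.add(_canonical_edge(pix(a), pix(b)))

    def merge_vertex(edge: Edge) -> int:
        """The lower endpoint of a saddle edge (the vertex whose insertion
        performed the merge) under the tie-broken total order."""
        a, b = lin(edge[0]), lin(edge[1])
        if (flat[a], -a) < (flat[b], -b):
            return a
        return b

    retained_maxima: set[int] = {lin(m) for m in essential}
    cancelled: dict[int, tuple[Edge, int]] = {}  # max -> (death edge, anchor)
    retained: list[tuple[Edge, int]] = []
    for pair, anchor in zip(pairs, anchors):
        if pair.persistence > 0 and pair.persistence >= delta:
            retained_maxima.add(lin(pair.birth_vertex))
            if min(flat[lin(pair.death_edge[0])], flat[lin(pair.death_edge[1])]) >= floor:
                graph.saddle_edges.add(pair.death_edge)
                retained.append((pair.death_edge, anchor))
        else:
            # cancelled pair: ascents passing through this maximum tunnel
            # across its death saddle and keep climbing on the far side
            cancelled[lin(pair.birth_vertex)] = (pair.death_edge, anchor)

    stack: list[int] = []

    def open_saddle(edge: Edge, anchor: int) -> None:
        """Add a saddle edge plus the anchor edge on the far side of its
        merge vertex, and queue ascents into both merged components."""
        v = merge_vertex(edge)
        u = lin(edge[0]) if lin(edge[0]) != v else lin(edge[1])
        add_edge(u, v)
        add_edge(anchor, v)
        stack.append(u)
        stack.append(v)
        stack.append(anchor)

    for edge, anchor in retained:
        open_saddle(edge, anchor)

    expanded: set[int] = set()
    walked = np.zeros(flat.size, dtype=bool)
    while stack:
        v = stack.pop()
        hit_walked = False
        while parent[v] != v:
            add_edge(v, parent[v])
            if walked[v]:
                hit_walked = True
                break
            walked[v] = True
            v = parent[v]
        if hit_walked:
            continue  # remainder of this ascent was traced earlier
        m = v  # a local maximum
        if m in retained_maxima:
            graph.maxima.add(pix(m))
            continue
        if m in expanded:
            continue
        expanded.add(m)
        edge, anchor = cancelled[m]
        if min(flat[lin(edge[0])], flat[lin(edge[1])]) < floor:
            continue
        open_saddle(edge, anchor)

    # plateaus of retained maxima (degenerate flat critical points)
    for m in sorted(retained_maxima):
        if flat[m] <= 0 or flat[m] < floor:
            continue
        plat = _plateau(values, m)
        graph.maxima.add(pix(m))
        plat_set = set(plat)
        for v in plat:
            for u in _neighbors(v, n_rows, n_cols):
                if u > v and u in plat_set:
                    add_edge(v, u)

    for node in graph.nodes:
        graph.node_density[node] = float(values[node])
    return graph
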