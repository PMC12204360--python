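"""From raw Morse graph to axon-fragment skeletons.

The raw Morse graph skeleton traces every retained ridge, including ridges
through background regions that bridge unrelated structures.  This module
applies the biological cleanup: intersect with a likelihood mask (Otsu by
default) to suppress false detections, extract per-component maximal spanning
trees (axons are trees), prune short low-curvature side branches ("haircut"),
decompose into skeletal fragments between critical points, and vectorize the
fragments as GeoJSON LineStrings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field

import networkx as nx
import numpy as np
from skimage.filters import threshold_otsu

from .morse import DensityField, MorseGraph, Pixel, _canonical_edge

__all__ = [
    "BinaryMask",
    "SkeletonGraph",
    "Fragment",
    "FragmentSet",
    "otsu_mask",
    "mask_graph",
    "max_spanning_forest",
    "haircut",
    "find_critical_points",
    "extract_fragments",
    "to_vector_document",
    "read_vector_document",
]


@dataclass(frozen=True)
class BinaryMask:
    """Boolean pixel mask, same shape as the density field it masks."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=bool))
        if self.values.ndim != 2:
            raise ValueError("mask must be 2D")


class SkeletonGraph(nx.Graph):
    """Undirected simple graph on pixel nodes, subgraph of the grid adjacency.

    Nodes are (row, col) pixel tuples with a ``density`` attribute; edges
    carry a ``weight`` attribute (mean of the endpoint densities).
    """


def skeleton_graph_from_morse(morse: MorseGraph) -> SkeletonGraph:
    """Convert a MorseGraph to a weighted SkeletonGraph."""
    g = SkeletonGraph()
    for u, v in sorted(morse.edges):
        du = morse.node_density.get(u, 0.0)
        dv = morse.node_density.get(v, 0.0)
        g.add_node(u, density=du)
        g.add_node(v, density=dv)
        g.add_edge(u, v, weight=0.5 * (du + dv))
    return g


@dataclass(frozen=True)
class Fragment:
    """A skeletal fragment: a path between two critical points (or a loop).

    ``vertices`` are ordered (row, col) coordinates in pixel units (floats
    allowed after coordinate transforms); ``length_um`` is its polyline
    length; ``kind`` labels the endpoint types, e.g. ("endpoint",
    "branchpoint") or ("loop", "loop").
    """

    vertices: tuple
    length_um: float
    kind: tuple[str, str] = ("endpoint", "endpoint")

    @property
    def n_edges(self) -> int:
        return len(self.vertices) - 1

    @property
    def closed(self) -> bool:
        return self.kind == ("loop", "loop")


@dataclass
class FragmentSet:
    """Collection of fragments sharing one pixel size."""

    fragments: list[Fragment] = dataclass_field(default_factory=list)
    pixel_size_um: float = 1.0

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    @property
    def total_length_um(self) -> float:
        return float(sum(f.length_um for f in self.fragments))


def polyline_length_um(vertices, pixel_size_um: float) -> float:
    v = np.asarray(vertices, dtype=np.float64)
    if len(v) < 2:
        return 0.0
    return float(np.sum(np.hypot(*(np.diff(v, axis=0).T))) * pixel_size_um)


def otsu_mask(likelihood: DensityField) -> BinaryMask:
    """Binarize a likelihood field at the threshold maximizing between-class
    variance over its 256-bin histogram.  Mask = values >= threshold."""
    values = likelihood.values
    if values.min() == values.max():
        raise ValueError("Otsu threshold undefined on a constant field")
    thr = threshold_otsu(values, nbins=256)
    return BinaryMask(values >= thr)


def mask_graph(graph: MorseGraph | SkeletonGraph, mask: BinaryMask) -> SkeletonGraph:
    """Remove graph nodes at mask-False pixels (with incident edges)."""
    if isinstance(graph, MorseGraph):
        if mask.values.shape != graph.shape:
            raise ValueError(f"mask shape {mask.values.shape} != field shape {graph.shape}")
        graph = skeleton_graph_from_morse(graph)
    keep = [n for n in graph.nodes if mask.values[n]]
    out = SkeletonGraph()
    out.add_nodes_from((n, graph.nodes[n]) for n in keep)
    for u, v, data in graph.edges(data=True):
        if mask.values[u] and mask.values[v]:
            out.add_edge(u, v, **data)
    return out


def max_spanning_forest(graph: SkeletonGraph) -> SkeletonGraph:
    """Per-component maximum-weight spanning tree (Kruskal).

    The node set is preserved; ties are broken by lexicographic edge index so
    the result is deterministic.
    """
    out = SkeletonGraph()
    out.add_nodes_from(graph.nodes(data=True))
    edges = sorted(
        graph.edges(data=True),
        key=lambda e: (-e[2].get("weight", 1.0),) + _canonical_edge(e[0], e[1]),
    )
    uf = nx.utils.UnionFind(graph.nodes)
    for u, v, data in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            out.add_edge(u, v, **data)
    return out


def _direction_changes(path: list[Pixel]) -> int:
    steps = [(b[0] - a[0], b[1] - a[1]) for a, b in zip(path, path[1:])]
    return sum(1 for a, b in zip(steps, steps[1:]) if a != b)


def haircut(graph: SkeletonGraph, max_len_px: int = 10) -> SkeletonGraph:
    """Prune short low-curvature terminal branches from a skeleton forest.

    Removes every branch-node-to-endpoint path of the *input* forest with at
    most ``max_len_px`` edges whose axial step directions change at most once
    (noise "hair": spurs connecting the real signal to nearby noise maxima).
    Branch nodes are retained; a single pass over the input graph is made.
    ``max_len_px == 0`` is the identity.
    """
    if max_len_px < 0:
        raise ValueError("max_len_px must be >= 0")
    if not nx.is_forest(graph):
        raise ValueError("haircut expects a forest; run max_spanning_forest first")
    degree = dict(graph.degree)
    to_remove: set[Pixel] = set()
    for node in sorted(n for n, d in degree.items() if d == 1):
        # walk inward from the endpoint to the first node of degree != 2
        path = [node]
        prev = None
        cur = node
        while True:
            nxt = [n for n in graph.neighbors(cur) if n != prev]
            if cur != node and degree[cur] != 2:
                break
            if not nxt:
                break  # whole component is a path with no branch node
            prev, cur = cur, nxt[0]
            path.append(cur)
        if degree[path[-1]] <= 2:
            continue  # no branch node at the far end: not a spur
        if len(path) - 1 <= max_len_px and _direction_changes(path) <= 1:
            to_remove.update(path[:-1])  # keep the branch node
    out = graph.copy()
    out.remove_nodes_from(to_remove)
    return out


def find_critical_points(graph: SkeletonGraph):
    """Branchpoints Bp (degree > 2), endpoints Ep (degree 1) and isolated
    nodes (degree 0), as three sorted lists."""
    bp, ep, iso = [], [], []
    for n, d in graph.degree:
        if d > 2:
            bp.append(n)
        elif d == 1:
            ep.append(n)
        elif d == 0:
            iso.append(n)
    return sorted(bp), sorted(ep), sorted(iso)


def extract_fragments(graph: SkeletonGraph, pixel_size_um: float = 1.0) -> FragmentSet:
    """Decompose a skeleton graph into fragments between critical points.

    Every edge belongs to exactly one fragment; each fragment is a maximal
    path whose interior nodes have degree 2.  Components that are pure cycles
    (no critical point) become one closed fragment anchored at their
    minimum-index node.
    """
    degree = dict(graph.degree)

    def node_kind(n) -> str:
        return "branchpoint" if degree[n] > 2 else ("endpoint" if degree[n] == 1 else "loop")

    used: set = set()
    fragments: list[Fragment] = []

    def walk(start, first) -> list:
        path = [start, first]
        used.add(_canonical_edge(start, first))
        prev, cur = start, first
        while degree[cur] == 2:
            nxt = [n for n in graph.neighbors(cur) if n != prev]
            if not nxt:
                break
            e = _canonical_edge(cur, nxt[0])
            if e in used:
                break
            used.add(e)
            prev, cur = cur, nxt[0]
            path.append(cur)
        return path

    critical = sorted(n for n, d in degree.items() if d != 2)
    for start in critical:
        for first in sorted(graph.neighbors(start)):
            if _canonical_edge(start, first) in used:
                continue
            path = walk(start, first)
            fragments.append(
                Fragment(
                    vertices=tuple(path),
                    length_um=polyline_length_um(path, pixel_size_um),
                    kind=(node_kind(path[0]), node_kind(path[-1])),
                )
            )

    # remaining edges belong to pure cycles of degree-2 nodes
    remaining = [e for e in graph.edges if _canonical_edge(*e) not in used]
    if remaining:
        sub = graph.edge_subgraph(remaining)
        for comp in sorted(nx.connected_components(sub), key=min):
            anchor = min(comp)
            first = sorted(sub.neighbors(anchor))[0]
            path = walk(anchor, first)  # returns to the anchor, already closed
            fragments.append(
                Fragment(
                    vertices=tuple(path),
                    length_um=polyline_length_um(path, pixel_size_um),
                    kind=("loop", "loop"),
                )
            )

    return FragmentSet(fragments=fragments, pixel_size_um=pixel_size_um)


# --------------------------------------------------------------------------
# GeoJSON vectorization (RFC 7946 structure; planar micrometre coordinates)

def to_vector_document(frags: FragmentSet, pixel_size_um: float | None = None) -> dict:
    """Vectorize fragments as a GeoJSON FeatureCollection of LineStrings.

    Coordinates are (x, y) = (col, row) * pixel_size in micrometres; each
    feature records length_um, n_vertices and the endpoint types.  The
    planar coordinate convention is documented in the top-level ``crs_note``.
    """
    if pixel_size_um is None:
        pixel_size_um = frags.pixel_size_um
    features = []
    for i, frag in enumerate(frags):
        coords = [[float(c * pixel_size_um), float(r * pixel_size_um)] for r, c in frag.vertices]
        features.append(
            {
                "type": "Feature",
                "id": i,
                "geometry": {"type": "LineString", "coordinates": coords},
                "properties": {
                    "length_um": float(frag.length_um),
                    "n_vertices": len(frag.vertices),
                    "endpoint_types": list(frag.kind),
                },
            }
        )
    return {
        "type": "FeatureCollection",
        "crs_note": "planar image coordinates in micrometres; x = column, y = row",
        "pixel_size_um": float(pixel_size_um),
        "features": features,
    }


def read_vector_document(doc: dict | str) -> FragmentSet:
    """Inverse of :func:`to_vector_document` (lossless round-trip)."""
    if isinstance(doc, str):
        with open(doc) as fh:
            doc = json.load(fh)
    pixel_size_um = float(doc.get("pixel_size_um", 1.0))

    def snap(c: float):
        # pixel-grid vertices round-trip exactly: int * pixel_size / pixel_size
        # may drift by one ulp, so snap near-integers back to the grid
        r = round(c)
        return r if abs(c - r) < 1e-9 else float(c)

    frags = []
    for feat in doc["features"]:
        coords = feat["geometry"]["coordinates"]
        vertices = tuple(
            (snap(y / pixel_size_um), snap(x / pixel_size_um)) for x, y in coords
        )
        props = feat.get("properties", {})
        frags.append(
            Fragment(
                vertices=vertices,
                length_um=float(props.get("length_um", polyline_length_um(vertices, pixel_size_um))),
                kind=tuple(props.get("endpoint_types", ("endpoint", "endpoint"))),
            )
        )
    return FragmentSet(fragments=frags, pixel_size_um=pixel_size_um)


def write_vector_document(frags: FragmentSet, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(to_vector_document(frags), fh, indent=None, separators=(",", ":"), sort_keys=True)
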