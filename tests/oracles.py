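"""Independent brute-force oracles used by the tests.

These deliberately re-derive results by the most literal method available
(boundary-matrix reduction, exhaustive search, enumeration) and share no code
with the implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def persistence_pairs_reduction(values: np.ndarray) -> list[tuple[float, float]]:
    """0-dim persistence of the superlevel filtration by boundary-matrix
    reduction on the grid's 1-skeleton.

    Works on g = -values (sublevel) with simplexwise order: cells sorted by
    (g, dim, index); vertex g = -value, edge g = max endpoint g.  Returns the
    multiset of finite (birth_value, death_value) pairs in the original
    (superlevel) scale, zero-persistence pairs dropped.
    """
    values = np.asarray(values, dtype=np.float64)
    n_rows, n_cols = values.shape
    n = values.size
    g_vertex = -values.ravel()

    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            v = r * n_cols + c
            if c + 1 < n_cols:
                edges.append((v, v + 1))
            if r + 1 < n_rows:
                edges.append((v, v + n_cols))

    # filtration positions: vertices by (g, 0, index); edges by (g, 1, index)
    cells = [("v", i) for i in range(n)] + [("e", i) for i in range(len(edges))]

    def g_of(cell):
        kind, i = cell
        if kind == "v":
            return g_vertex[i]
        a, b = edges[i]
        return max(g_vertex[a], g_vertex[b])

    def sort_key(cell):
        kind, i = cell
        return (g_of(cell), 0 if kind == "v" else 1, i)

    cells.sort(key=sort_key)
    position = {cell: k for k, cell in enumerate(cells)}

    # reduce edge columns over GF(2); columns indexed by filtration position
    low_of: dict[int, set[int]] = {}  # low vertex position -> reduced column
    pairs = []
    for cell in cells:
        if cell[0] != "e":
            continue
        a, b = edges[cell[1]]
        col = {position[("v", a)], position[("v", b)]}
        while col:
            low = max(col)
            if low not in low_of:
                break
            col = col ^ low_of[low]
        if col:
            low = max(col)
            low_of[low] = col
            birth_vertex = cells[low][1]
            birth_value = values.ravel()[birth_vertex]
            death_value = -g_of(cell)
            if birth_value > death_value:
                pairs.append((float(birth_value), float(death_value)))
    return sorted(pairs)


def otsu_threshold_exhaustive(values: np.ndarray, nbins: int = 256) -> float:
    """Between-class-variance search over all nbins candidate thresholds."""
    values = np.asarray(values, dtype=np.float64).ravel()
    counts, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_var, best_thr = -1.0, centers[0]
    total = counts.sum()
    for t in range(1, nbins):
        w0 = counts[:t].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:t] * centers[:t]).sum() / w0
        mu1 = (counts[t:] * centers[t:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[t - 1]
    return float(best_thr)


def spanning_forest_max_weight(graph) -> float:
    """Maximum total spanning-forest weight by exhaustive enumeration
    (graphs with <= 8 nodes)."""
    import networkx as nx

    best = 0.0
    for comp_nodes in nx.connected_components(graph):
        comp = graph.subgraph(comp_nodes)
        n_edges_needed = comp.number_of_nodes() - 1
        comp_best = -np.inf
        edge_list = list(comp.edges(data="weight"))
        for subset in itertools.combinations(edge_list, n_edges_needed):
            sub = nx.Graph()
            sub.add_nodes_from(comp.nodes)
            sub.add_edges_from((u, v) for u, v, _ in subset)
            if nx.is_connected(sub):
                comp_best = max(comp_best, sum(w for _, _, w in subset))
        if n_edges_needed == 0:
            comp_best = 0.0
        best += comp_best
    return best


def integrate_labels_loop(density: np.ndarray, labels: np.ndarray, voxel_volume: float):
    """Per-label total length by an explicit per-voxel loop."""
    totals: dict[int, float] = {}
    it = np.nditer(labels, flags=["multi_index"])
    for lab in it:
        lab = int(lab)
        if lab == 0:
            continue
        totals[lab] = totals.get(lab, 0.0) + density[it.multi_index] * voxel_volume
    return totals
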