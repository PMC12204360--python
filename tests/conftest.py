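import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dmskel import DensityField, SkeletonGraph


def make_skeleton_graph(edges, weights=None, densities=None) -> SkeletonGraph:
    """Build a SkeletonGraph from an edge list of (row, col) node pairs."""
    g = SkeletonGraph()
    for i, (u, v) in enumerate(edges):
        w = 1.0 if weights is None else weights[i]
        g.add_edge(tuple(u), tuple(v), weight=w)
    for n in g.nodes:
        g.nodes[n]["density"] = 1.0 if densities is None else densities.get(n, 1.0)
    return g


def path_edges(points):
    return list(zip(points, points[1:]))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def ridge_field():
    """Noiseless straight bright ridge: one row at 1 on a 0 background."""
    img = np.zeros((7, 9))
    img[3, :] = 1.0
    return DensityField(img)


@pytest.fixture
def y_gap_field():
    """Noiseless Y-junction with a 2-px stretch of reduced (nonzero)
    intensity along one arm."""
    img = np.zeros((21, 21))
    img[10, 1:11] = 1.0  # stem
    for i in range(1, 9):  # two staircase arms from the junction at (10, 10)
        img[10 - i, 10 + i] = 1.0
        img[10 - i + 1, 10 + i] = 1.0
        img[10 + i, 10 + i] = 1.0
        img[10 + i - 1, 10 + i] = 1.0
    img[13, 13] = 0.3  # the gap
    img[12, 13] = 0.3
    return DensityField(img)
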