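"""Tests for masking, spanning forests, haircut pruning, fragment
decomposition and GeoJSON vectorization."""

import json

import networkx as nx
import numpy as np
import pytest

from dmskel import (
    BinaryMask,
    DensityField,
    extract_fragments,
    extract_morse_graph,
    find_critical_points,
    haircut,
    mask_graph,
    max_spanning_forest,
    otsu_mask,
    read_vector_document,
    to_vector_document,
)
from dmskel.postprocess import FragmentSet, skeleton_graph_from_morse
from conftest import make_skeleton_graph, path_edges
from oracles import otsu_threshold_exhaustive, spanning_forest_max_weight


class TestOtsuMask:
    def test_perfectly_bimodal(self):
        img = np.full((10, 10), 0.1)
        img[:, 5:] = 0.9
        mask = otsu_mask(DensityField(img))
        np.testing.assert_array_equal(mask.values, img >= 0.5)

    def test_binary_field(self):
        img = np.zeros((8, 8))
        img[2:4, 2:6] = 1.0
        mask = otsu_mask(DensityField(img))
        np.testing.assert_array_equal(mask.values, img == 1.0)

    def test_matches_exhaustive_search(self, rng):
        values = np.concatenate(
            [rng.normal(0.2, 0.05, 50), rng.normal(0.8, 0.05, 50)]
        ).clip(0, 1).reshape(10, 10)
        mask = otsu_mask(DensityField(values))
        thr = otsu_threshold_exhaustive(values)
        # same partition even if the two searches report slightly different
        # representative thresholds inside the empty histogram gap
        np.testing.assert_array_equal(mask.values, values >= thr)

    def test_constant_field_rejected(self):
        with pytest.raises(ValueError):
            otsu_mask(DensityField(np.full((5, 5), 0.3)))


class TestMaskGraph:
    def _ridge_graph(self):
        img = np.zeros((5, 9))
        img[2, :] = 1.0
        return extract_morse_graph(DensityField(img), delta=0.1)

    def test_all_true_mask_is_identity(self):
        g = self._ridge_graph()
        masked = mask_graph(g, BinaryMask(np.ones((5, 9), bool)))
        assert set(map(frozenset, masked.edges)) == set(map(frozenset, g.edges))

    def test_all_false_mask_empties_graph(self):
        masked = mask_graph(self._ridge_graph(), BinaryMask(np.zeros((5, 9), bool)))
        assert masked.number_of_edges() == 0

    def test_interior_removal_splits_component(self):
        mask = np.ones((5, 9), bool)
        mask[2, 4] = False
        masked = mask_graph(self._ridge_graph(), BinaryMask(mask))
        assert nx.number_connected_components(masked) == 2

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mask_graph(self._ridge_graph(), BinaryMask(np.ones((4, 4), bool)))


class TestMaxSpanningForest:
    def test_tree_input_unchanged(self):
        g = make_skeleton_graph(path_edges([(0, 0), (0, 1), (0, 2), (1, 2)]))
        out = max_spanning_forest(g)
        assert set(map(frozenset, out.edges)) == set(map(frozenset, g.edges))

    def test_cycle_drops_lightest_edge(self):
        edges = [((0, 0), (0, 1)), ((0, 1), (1, 1)), ((1, 1), (1, 0)), ((1, 0), (0, 0))]
        g = make_skeleton_graph(edges, weights=[1.0, 1.0, 1.0, 0.5])
        out = max_spanning_forest(g)
        assert not out.has_edge((1, 0), (0, 0))
        assert out.number_of_edges() == 3

    def test_edge_count_equals_nodes_minus_components(self, rng):
        # random grid-ish graphs
        for _ in range(20):
            nodes = [(i, j) for i in range(4) for j in range(4)]
            edges = []
            for i, j in nodes:
                if j < 3 and rng.random() < 0.6:
                    edges.append((((i, j)), ((i, j + 1))))
                if i < 3 and rng.random() < 0.6:
                    edges.append((((i, j)), ((i + 1, j))))
            if not edges:
                continue
            g = make_skeleton_graph(edges, weights=list(rng.random(len(edges))))
            out = max_spanning_forest(g)
            n_comp = nx.number_connected_components(g)
            assert out.number_of_edges() == g.number_of_nodes() - n_comp

    def test_optimal_weight_vs_enumeration(self, rng):
        for _ in range(10):
            nodes = [(0, j) for j in range(6)]
            g = make_skeleton_graph(
                [(nodes[i], nodes[j]) for i in range(6) for j in range(i + 1, 6) if rng.random() < 0.5]
                or [(nodes[0], nodes[1])],
            )
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.random())
            out = max_spanning_forest(g)
            got = sum(d["weight"] for _, _, d in out.edges(data=True))
            assert got == pytest.approx(spanning_forest_max_weight(g), rel=1e-12)


class TestHaircut:
    def _spine_with_spur(self, spur_points):
        spine = [(5, c) for c in range(20)]
        edges = path_edges(spine) + path_edges([(5, 10)] + spur_points)
        return make_skeleton_graph(edges)

    def test_straight_short_spur_removed(self):
        spur = [(5 - k, 10) for k in range(1, 6)]  # 5 edges straight up
        out = haircut(self._spine_with_spur(spur), max_len_px=10)
        assert all(not out.has_node(p) for p in spur)
        assert out.has_node((5, 10))  # branch node kept

    def test_long_spur_retained(self):
        spur = [(5 - k, 10) for k in range(1, 5)] + [(1, 10 + k) for k in range(1, 12)]
        g = self._spine_with_spur(spur)
        out = haircut(g, max_len_px=10)
        assert all(out.has_node(p) for p in spur)

    def test_one_direction_change_removed_staircase_retained(self):
        l_spur = [(4, 10), (3, 10), (2, 10), (2, 11), (2, 12), (2, 13)]  # one turn
        out = haircut(self._spine_with_spur(l_spur), max_len_px=10)
        assert all(not out.has_node(p) for p in l_spur)

        stair = [(4, 10), (4, 11), (3, 11), (3, 12), (2, 12), (2, 13)]  # 4 turns
        out = haircut(self._spine_with_spur(stair), max_len_px=10)
        assert all(out.has_node(p) for p in stair)

    def test_zero_length_is_identity(self):
        g = self._spine_with_spur([(4, 10), (3, 10)])
        out = haircut(g, max_len_px=0)
        assert set(out.edges) == set(g.edges)

    def test_non_forest_rejected(self):
        cycle = make_skeleton_graph(
            path_edges([(0, 0), (0, 1), (1, 1), (1, 0), (0, 0)])
        )
        with pytest.raises(ValueError):
            haircut(cycle)

    def test_never_disconnects_surviving_nodes(self, rng):
        # random trees: after haircut every surviving component was a whole
        # component (minus spurs) of the input
        for _ in range(10):
            g = nx.random_labeled_tree(15, seed=int(rng.integers(1 << 30)))
            sk = make_skeleton_graph([((0, u), (0, v)) for u, v in g.edges])
            out = haircut(sk, max_len_px=3)
            for n in out.nodes:
                assert out.degree[n] <= sk.degree[n]
            assert nx.number_connected_components(out) <= nx.number_connected_components(sk)


class TestCriticalPoints:
    def test_simple_path(self):
        g = make_skeleton_graph(path_edges([(0, c) for c in range(6)]))
        bp, ep, iso = find_critical_points(g)
        assert bp == [] and iso == []
        assert ep == [(0, 0), (0, 5)]

    def test_y_junction(self):
        center = (5, 5)
        arms = [[(5, 5 + k) for k in range(1, 4)],
                [(5 - k, 5) for k in range(1, 4)],
                [(5 + k, 5) for k in range(1, 4)]]
        edges = []
        for arm in arms:
            edges += path_edges([center] + arm)
        bp, ep, iso = find_critical_points(make_skeleton_graph(edges))
        assert bp == [center]
        assert len(ep) == 3

    def test_pure_cycle_has_no_critical_points(self):
        g = make_skeleton_graph(path_edges([(0, 0), (0, 1), (1, 1), (1, 0), (0, 0)]))
        bp, ep, iso = find_critical_points(g)
        assert bp == [] and ep == [] and iso == []


class TestExtractFragments:
    def test_path_single_fragment(self):
        g = make_skeleton_graph(path_edges([(0, c) for c in range(11)]))
        frags = extract_fragments(g, pixel_size_um=0.5)
        assert len(frags) == 1
        assert frags.fragments[0].length_um == pytest.approx(10 * 0.5)

    def test_y_fragments_conserve_edges(self):
        center = (9, 9)
        edges = []
        for darm in [(0, 1), (1, 0), (-1, 0)]:
            arm = [(9 + darm[0] * k, 9 + darm[1] * k) for k in range(1, 6)]
            edges += path_edges([center] + arm)
        g = make_skeleton_graph(edges)
        frags = extract_fragments(g)
        assert len(frags) == 3
        assert sum(f.n_edges for f in frags) == 15

    def test_two_components_two_fragments(self):
        g = make_skeleton_graph(
            path_edges([(0, 0), (0, 1), (0, 2)]) + path_edges([(5, 0), (5, 1)])
        )
        assert len(extract_fragments(g)) == 2

    def test_pure_cycle_single_closed_fragment(self):
        g = make_skeleton_graph(path_edges([(0, 0), (0, 1), (1, 1), (1, 0), (0, 0)]))
        frags = extract_fragments(g)
        assert len(frags) == 1
        frag = frags.fragments[0]
        assert frag.closed
        assert frag.vertices[0] == frag.vertices[-1] == (0, 0)
        assert frag.n_edges == 4

    def test_edge_conservation_on_random_graphs(self, rng):
        for _ in range(15):
            edges = set()
            for i in range(5):
                for j in range(5):
                    if j < 4 and rng.random() < 0.55:
                        edges.add(((i, j), (i, j + 1)))
                    if i < 4 and rng.random() < 0.55:
                        edges.add(((i, j), (i + 1, j)))
            if not edges:
                continue
            g = make_skeleton_graph(sorted(edges))
            frags = extract_fragments(g)
            assert sum(f.n_edges for f in frags) == g.number_of_edges()


class TestVectorDocument:
    def test_lengths_scaled_to_um(self):
        g = make_skeleton_graph(path_edges([(0, c) for c in range(11)]))
        frags = extract_fragments(g, pixel_size_um=0.46)
        doc = to_vector_document(frags)
        assert len(doc["features"]) == 1
        assert doc["features"][0]["properties"]["length_um"] == pytest.approx(4.6)
        xs = [xy[0] for xy in doc["features"][0]["geometry"]["coordinates"]]
        assert xs[1] - xs[0] == pytest.approx(0.46)

    def test_empty_set_valid_collection(self):
        doc = to_vector_document(FragmentSet(fragments=[], pixel_size_um=1.0))
        assert doc["type"] == "FeatureCollection"
        assert doc["features"] == []

    def test_round_trip_byte_identical(self):
        g = make_skeleton_graph(
            path_edges([(0, c) for c in range(5)]) + path_edges([(2, 0), (2, 1), (3, 1)])
        )
        frags = extract_fragments(g, pixel_size_um=0.46)
        doc1 = to_vector_document(frags)
        doc2 = to_vector_document(read_vector_document(doc1))
        assert json.dumps(doc1, sort_keys=True) == json.dumps(doc2, sort_keys=True)


def test_pipeline_geojson_deterministic(tmp_path):
    """Identical inputs and config must produce identical GeoJSON bytes."""
    import tifffile

    from dmskel import PhantomSpec, generate_phantom, run_pipeline
    from dmskel.pipeline import PipelineConfig

    field, _, _ = generate_phantom(PhantomSpec(seed=3, shape=(64, 64), n_trees=1, steps_per_tree=60))
    img_path = tmp_path / "tile.tif"
    tifffile.imwrite(img_path, field.values.astype(np.float32))
    cfg = PipelineConfig()
    blobs = []
    for run in range(2):
        out = tmp_path / f"run{run}"
        run_pipeline(cfg, [img_path], out)
        blobs.append((out / "tile.geojson").read_bytes())
    assert blobs[0] == blobs[1]
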