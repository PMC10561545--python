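"""k-NN graph, minimum spanning tree and deterministic 2-D layout."""

import itertools

import networkx as nx
import numpy as np
import pytest

from alchemap.treemap_layout import (
    build_treemap,
    knn_graph,
    layout_tree,
    minimum_spanning_tree,
)


def brute_force_mst_weight(graph: nx.Graph) -> float:
    """Minimum total weight over all spanning trees, by exhaustive enumeration."""
    nodes = list(graph.nodes)
    edges = [(u, v, d["weight"]) for u, v, d in graph.edges(data=True)]
    best = np.inf
    for subset in itertools.combinations(edges, len(nodes) - 1):
        t = nx.Graph()
        t.add_nodes_from(nodes)
        t.add_weighted_edges_from(subset)
        if nx.is_connected(t):
            best = min(best, sum(w for _, _, w in subset))
    return best


def random_connected_graph(rng, n_nodes, n_edges):
    g = nx.Graph()
    nodes = list(range(n_nodes))
    g.add_nodes_from(nodes)
    # spanning chain first, then extra random edges
    for i in range(n_nodes - 1):
        g.add_edge(i, i + 1, weight=float(rng.uniform(0, 1)))
    while g.number_of_edges() < n_edges:
        u, v = rng.choice(n_nodes, 2, replace=False)
        if not g.has_edge(u, v):
            g.add_edge(int(u), int(v), weight=float(rng.uniform(0, 1)))
    return g


class TestKnnGraph:
    def test_small_n_gives_complete_graph(self, caplog):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        with caplog.at_level("WARNING"):
            g = knn_graph(d, ["a", "b", "c"], k=20)
        assert g.graph.number_of_edges() == 3

    def test_k1_links_argmin(self):
        d = np.array([[0, 0.1, 0.5], [0.1, 0, 0.4], [0.5, 0.4, 0]])
        g = knn_graph(d, ["a", "b", "c"], k=1)
        assert set(map(frozenset, g.graph.edges)) == {frozenset({"a", "b"}),
                                                      frozenset({"b", "c"})}

    def test_brute_force_sort_oracle(self):
        rng = np.random.default_rng(7)
        d = rng.uniform(0.01, 1, (10, 10))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"n{i}" for i in range(10)]
        k = 3
        g = knn_graph(d, ids, k=k)
        expected = set()
        for i in range(10):
            order = sorted((j for j in range(10) if j != i),
                           key=lambda j: (d[i, j], ids[j]))[:k]
            for j in order:
                expected.add(frozenset({ids[i], ids[j]}))
        assert set(map(frozenset, g.graph.edges)) == expected

    def test_single_node_raises(self):
        with pytest.raises(ValueError):
            knn_graph(np.zeros((1, 1)), ["a"], k=1)

    def test_no_self_loops_weights_in_range(self):
        d = np.random.default_rng(0).uniform(0, 1, (6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        g = knn_graph(d, list("abcdef"), k=2)
        assert all(u != v for u, v in g.graph.edges)
        assert all(0 <= w["weight"] <= 1 for _, _, w in g.graph.edges(data=True))


class TestMinimumSpanningTree:
    def test_triangle(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 2.0), ("a", "c", 3.0)])
        mst = minimum_spanning_tree(g)
        assert mst.total_weight == 3.0
        assert len(mst.mst_edges) == 2

    def test_tree_returned_unchanged(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("a", "b", 0.3), ("b", "c", 0.7)])
        mst = minimum_spanning_tree(g)
        assert {frozenset({u, v}) for u, v, _ in mst.mst_edges} == \
               {frozenset({"a", "b"}), frozenset({"b", "c"})}

    def test_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            g = random_connected_graph(rng, n, min(n + 4, n * (n - 1) // 2))
            mst = minimum_spanning_tree(g)
            assert mst.total_weight == pytest.approx(brute_force_mst_weight(g))

    def test_edge_count_equals_nodes_minus_components(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("a", "b", 1.0), ("c", "d", 1.0), ("d", "e", 2.0)])
        g.add_node("lonely")
        mst = minimum_spanning_tree(g)
        assert len(mst.mst_edges) == 6 - 3
        assert len(set(mst.components.values())) == 3

    def test_weight_invariant_under_edge_permutation(self):
        rng = np.random.default_rng(5)
        g = random_connected_graph(rng, 7, 12)
        w1 = minimum_spanning_tree(g).total_weight
        h = nx.Graph()
        h.add_nodes_from(g.nodes)
        edges = list(g.edges(data=True))
        for u, v, d in reversed(edges):
            h.add_edge(u, v, **d)
        assert minimum_spanning_tree(h).total_weight == pytest.approx(w1)

    def test_cut_property(self):
        rng = np.random.default_rng(9)
        g = random_connected_graph(rng, 8, 14)
        mst = minimum_spanning_tree(g)
        t = nx.Graph()
        t.add_nodes_from(g.nodes)
        t.add_weighted_edges_from(mst.mst_edges)
        for u, v, w in mst.mst_edges:
            t.remove_edge(u, v)
            side = nx.node_connected_component(t, u)
            crossing = [d["weight"] for x, y, d in g.edges(data=True)
                        if (x in side) != (y in side)]
            assert w == pytest.approx(min(crossing))
            t.add_edge(u, v, weight=w)


class TestLayout:
    def test_single_node_at_origin(self):
        g = nx.Graph()
        g.add_node("only")
        layout = layout_tree(minimum_spanning_tree(g))
        assert layout.coords["only"] == (0.0, 0.0)

    def test_path_of_three_distinct_points(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 1.0)])
        layout = layout_tree(minimum_spanning_tree(g))
        assert len(set(layout.coords.values())) == 3

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(0.01, 1, (8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"n{i}" for i in range(8)]
        l1 = build_treemap(d, ids, k=3, seed=0)
        l2 = build_treemap(d, ids, k=3, seed=0)
        assert l1.coords == l2.coords
        assert l1.mst_edges == l2.mst_edges

    def test_adjacent_nodes_never_coincide(self):
        rng = np.random.default_rng(4)
        g = random_connected_graph(rng, 10, 15)
        layout = layout_tree(minimum_spanning_tree(g))
        for u, v, _ in layout.mst_edges:
            assert layout.coords[u] != layout.coords[v]

    def test_disconnected_components_in_disjoint_boxes(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("a", "b", 1.0), ("a", "c", 1.0)])
        g.add_weighted_edges_from([("x", "y", 1.0), ("y", "z", 1.0)])
        layout = layout_tree(minimum_spanning_tree(g))
        xs0 = [layout.coords[n][0] for n in "abc"]
        xs1 = [layout.coords[n][0] for n in "xyz"]
        assert max(xs0) < min(xs1) or max(xs1) < min(xs0)

    def test_all_coordinates_finite(self):
        rng = np.random.default_rng(6)
        g = random_connected_graph(rng, 12, 18)
        layout = layout_tree(minimum_spanning_tree(g))
        arr = np.array(list(layout.coords.values()))
        assert np.all(np.isfinite(arr))


def test_export_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    d = rng.uniform(0.01, 1, (5, 5))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    layout = build_treemap(d, [f"n{i}" for i in range(5)], k=2)
    from alchemap.treemap_layout import export_coordinates_tsv, export_graphml
    export_graphml(layout, tmp_path / "t.graphml")
    export_coordinates_tsv(layout, tmp_path / "t.tsv")
    g = nx.read_graphml(tmp_path / "t.graphml")
    assert g.number_of_nodes() == 5
    assert (tmp_path / "t.tsv").read_text().startswith("node\tx\ty\tcomponent")
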