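"""Minimal spanning tree over SOM codebook vectors, plus 2-D layout.

The MST links each node to its nearest neighbors in marker space,
organizing the 100 SOM nodes into branches that follow hematopoietic
differentiation — the display backbone of the whole paradigm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform, pdist

from .exceptions import ValidationError
from .som import SOMModel


@dataclass
class MSTGraph:
    """Minimum spanning tree over node codebook vectors.

    ``edges`` holds ``(node_a, node_b, weight)`` with ``node_a < node_b``
    and Euclidean weights in scaled space; ``layout`` maps node id to 2-D
    display coordinates once computed.
    """

    n_nodes: int
    edges: list[tuple[int, int, float]]
    layout: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_nodes >= 1 and len(self.edges) != self.n_nodes - 1:
            raise ValidationError(
                f"{len(self.edges)} edges for {self.n_nodes} nodes; a spanning "
                f"tree needs {self.n_nodes - 1}"
            )

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(self.edges)
        return g


def build_mst(model: SOMModel) -> MSTGraph:
    """Minimum spanning tree of the complete codebook graph.

    Kruskal's algorithm on Euclidean distances; equal-weight edges are
    resolved in lexicographic ``(node_a, node_b)`` order (networkx's sort
    is stable and edges are inserted in that order).
    """
    n = model.n_nodes
    if n < 1:
        raise ValidationError("model has no nodes")
    if n == 1:
        return MSTGraph(n_nodes=1, edges=[])
    d = squareform(pdist(model.codebook))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for a in range(n):
        for b in range(a + 1, n):
            g.add_edge(a, b, weight=float(d[a, b]))
    t = nx.minimum_spanning_tree(g, algorithm="kruskal")
    edges = sorted(
        (min(a, b), max(a, b), float(w)) for a, b, w in t.edges.data("weight")
    )
    return MSTGraph(n_nodes=n, edges=edges)


def layout_mst(tree: MSTGraph, seed: int = 0) -> dict[int, tuple[float, float]]:
    """Seeded force-directed 2-D embedding of the tree.

    Deterministic for a given seed; coordinates are finite and pairwise
    distinct.  The layout is stored on the tree and returned.
    """
    g = tree.to_graph()
    if tree.n_nodes == 1:
        coords = {0: (0.0, 0.0)}
    else:
        pos = nx.spring_layout(g, seed=int(seed), weight="weight", iterations=100)
        coords = {int(k): (float(v[0]), float(v[1])) for k, v in pos.items()}
    pts = np.array(list(coords.values()))
    if not np.isfinite(pts).all():
        raise ValidationError("layout produced non-finite coordinates")
    # force-directed layouts essentially never collide, but guarantee it
    seen: dict[tuple[float, float], int] = {}
    for node in sorted(coords):
        p = coords[node]
        while p in seen:
            p = (p[0] + 1e-9 * (node + 1), p[1])
        seen[p] = node
        coords[node] = p
    tree.layout = coords
    return coords
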