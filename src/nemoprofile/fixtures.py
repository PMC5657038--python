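"""Deterministic fixture graphs and synthetic generators.

The headline fixture ``fixture_f9`` is a 9-node, 10-edge undirected graph
whose size-3 census is 14 path instances and 2 triangle instances ({1,2,3}
and {3,8,9}), 16 connected induced 3-subgraphs in total.  It is the worked
example every module is exercised against.  The edge list is a
reconstruction consistent with all of those counts and instance sets (the
original is only available as a drawing); uniqueness of the reconstruction
is not claimed.
"""

from __future__ import annotations

import numpy as np

from .graph import Graph

__all__ = ["fixture_f9", "F9_EDGES", "complete_graph", "path_graph", "star_graph", "random_graph"]

F9_EDGES = [
    (1, 2), (1, 3), (2, 3), (2, 4), (2, 5),
    (2, 6), (3, 8), (3, 9), (6, 7), (8, 9),
]


def fixture_f9() -> Graph:
    """The 9-vertex / 10-edge worked-example graph (labels "1".."9")."""
    return Graph.from_edges(F9_EDGES, directed=False, nodes=range(1, 10))


def complete_graph(n: int, directed: bool = False) -> Graph:
    """K_n (all mutual arcs when directed); labels "0".."n-1"."""
    edges = [(i, j) for i in range(n) for j in range(n) if i != j and (directed or i < j)]
    return Graph.from_edges(edges, directed=directed, nodes=range(n))


def path_graph(n: int) -> Graph:
    """Undirected path 0-1-...-(n-1)."""
    return Graph.from_edges([(i, i + 1) for i in range(n - 1)], nodes=range(n))


def star_graph(n: int) -> Graph:
    """Undirected star: hub 0 joined to n-1 leaves."""
    return Graph.from_edges([(0, i) for i in range(1, n)], nodes=range(n))


def random_graph(n: int, edge_prob: float, directed: bool = False, seed: int = 0) -> Graph:
    """Erdős–Rényi G(n, p), deterministic for a given seed."""
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(n) for j in range(n) if (i < j if not directed else i != j)]
    draws = rng.random(len(pairs))
    edges = [pair for pair, x in zip(pairs, draws) if x < edge_prob]
    return Graph.from_edges(edges, directed=directed, nodes=range(n))
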