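"""Exact enumeration of connected induced k-subgraphs (ESU).

ESU anchors every subgraph at its minimum-index node: starting from each
root v, the candidate extension set holds only nodes with index greater
than v that neighbor the growing subgraph but are *exclusive* neighbors —
not adjacent to any earlier-chosen node.  That discipline is what makes
each connected induced k-node subgraph come out exactly once.

Directed graphs are enumerated on their underlying undirected skeleton
(union of arc directions); direction matters only when instances are
classified into patterns.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Iterator

from .graph import Graph

__all__ = ["enumerate_subgraphs", "brute_force_enumerate"]

_BRUTE_FORCE_GUARD = 10**6


def enumerate_subgraphs(g: Graph, k: int) -> Iterator[tuple[int, ...]]:
    """Yield every connected induced k-subgraph of ``g`` exactly once.

    Each subgraph is emitted as a sorted tuple of internal node indices.
    Emission order is a pure function of the graph and k (roots ascending,
    extension candidates consumed in ascending index order).

    Raises
    ------
    ValueError
        If k < 2 or k > number of nodes.
    """
    n = g.n
    if k < 2 or k > n:
        raise ValueError(f"k must satisfy 2 <= k <= n (got k={k}, n={n})")
    nbrs = [g.neighbors(v) for v in range(n)]

    def extend(sub: list[int], ext: set[int], closed: set[int]) -> Iterator[tuple[int, ...]]:
        if len(sub) == k:
            yield tuple(sorted(sub))
            return
        pending = sorted(ext)
        for i, w in enumerate(pending):
            # exclusive neighbors of w: > root, unseen by the current subgraph
            new_ext = set(pending[i + 1:])
            for u in nbrs[w]:
                if u > sub[0] and u not in closed:
                    new_ext.add(u)
            sub.append(w)
            yield from extend(sub, new_ext, closed | {w} | nbrs[w])
            sub.pop()

    for v in range(n):
        root_ext = {u for u in nbrs[v] if u > v}
        yield from extend([v], root_ext, {v} | nbrs[v])


def brute_force_enumerate(g: Graph, k: int) -> Iterator[tuple[int, ...]]:
    """Oracle enumeration: filter all k-subsets for connectedness.

    Only intended for tests and tiny graphs; guarded at C(n, k) <= 10^6.
    """
    n = g.n
    if k < 2 or k > n:
        raise ValueError(f"k must satisfy 2 <= k <= n (got k={k}, n={n})")
    if comb(n, k) > _BRUTE_FORCE_GUARD:
        raise ValueError(f"C({n},{k}) exceeds brute-force guard of {_BRUTE_FORCE_GUARD}")
    for subset in combinations(range(n), k):
        if is_connected_subset(g, subset):
            yield subset


def is_connected_subset(g: Graph, nodes: tuple[int, ...]) -> bool:
    """True if ``nodes`` induces a (weakly) connected subgraph of ``g``."""
    node_set = set(nodes)
    stack = [nodes[0]]
    seen = {nodes[0]}
    while stack:
        v = stack.pop()
        for u in g.neighbors(v):
            if u in node_set and u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == len(node_set)
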