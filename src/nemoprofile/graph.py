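"""Graph data model and plain-text edge-list I/O.

Networks arrive as edge lists (one edge per line, whitespace-separated
endpoint labels, the dialect used by FANMOD and SNAP exports of PPI data).
Node labels are arbitrary strings — protein accessions, integers, whatever
the source uses.  All computation downstream works on contiguous internal
indices ``0..n-1`` assigned in order of first appearance; every output maps
back to the original labels.

Graphs are simple: no self-loops, no duplicate edges.  An undirected edge is
stored once and queryable from both endpoints; a directed graph may contain
the mutual pair ``u->v`` and ``v->u``.
"""

from __future__ import annotations

import logging
from typing import IO, Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

__all__ = ["Graph", "EdgeListParseError", "read_edge_list", "write_edge_list", "induced_subgraph"]


class EdgeListParseError(ValueError):
    """Raised for malformed or empty edge-list input."""


class Graph:
    """Simple directed or undirected graph over contiguous integer indices.

    Parameters
    ----------
    directed:
        Whether edges are arcs.  Undirected adjacency is kept symmetric.

    Attributes
    ----------
    node_labels:
        Original text label of each internal index, in index order.
    edge_count:
        Number of stored edges (an undirected edge counts once).
    parent_index:
        For graphs produced by :func:`induced_subgraph`, the original index
        of each node in the parent graph; ``None`` otherwise.
    """

    __slots__ = ("directed", "node_labels", "_label_to_index", "_out", "_in", "edge_count", "parent_index")

    def __init__(self, directed: bool = False):
        self.directed = bool(directed)
        self.node_labels: list[str] = []
        self._label_to_index: dict[str, int] = {}
        self._out: list[set[int]] = []   # neighbor sets; out-neighbors when directed
        self._in: list[set[int]] = []    # in-neighbors; aliases _out entries when undirected
        self.edge_count = 0
        self.parent_index: list[int] | None = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[object, object]], directed: bool = False,
                   nodes: Iterable[object] | None = None) -> "Graph":
        """Build a graph from (u, v) label pairs; labels are str()-ified.

        ``nodes`` may pre-register isolated nodes / fix the index order.
        Self-loops and duplicate edges are silently ignored.
        """
        g = cls(directed)
        if nodes is not None:
            for u in nodes:
                g.add_node(str(u))
        for u, v in edges:
            g.add_edge(str(u), str(v))
        return g

    def add_node(self, label: str) -> int:
        """Register ``label`` if new; return its internal index."""
        idx = self._label_to_index.get(label)
        if idx is None:
            idx = len(self.node_labels)
            self._label_to_index[label] = idx
            self.node_labels.append(label)
            out: set[int] = set()
            self._out.append(out)
            self._in.append(set() if self.directed else out)
        return idx

    def add_edge(self, u_label: str, v_label: str) -> bool:
        """Add an edge by labels; returns False for loops and duplicates."""
        u = self.add_node(u_label)
        v = self.add_node(v_label)
        return self._add_edge_idx(u, v)

    def _add_edge_idx(self, u: int, v: int) -> bool:
        if u == v or v in self._out[u]:
            return False
        self._out[u].add(v)
        self._in[v].add(u)
        self.edge_count += 1
        return True

    def _remove_edge_idx(self, u: int, v: int) -> None:
        self._out[u].remove(v)
        self._in[v].remove(u)
        self.edge_count -= 1

    # -- queries ------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.node_labels)

    def index_of(self, label: str) -> int:
        return self._label_to_index[label]

    def has_edge(self, u: int, v: int) -> bool:
        """Arc u->v when directed, edge {u,v} when undirected."""
        return v in self._out[u]

    def out_neighbors(self, v: int) -> set[int]:
        return self._out[v]

    def in_neighbors(self, v: int) -> set[int]:
        return self._in[v]

    def neighbors(self, v: int) -> set[int]:
        """Neighbors in the underlying undirected skeleton."""
        if self.directed:
            return self._out[v] | self._in[v]
        return self._out[v]

    def degree_sequence(self) -> tuple:
        """Sorted degree multiset; (in, out) pairs per node when directed."""
        if self.directed:
            return tuple(sorted((len(self._in[v]), len(self._out[v])) for v in range(self.n)))
        return tuple(sorted(len(self._out[v]) for v in range(self.n)))

    def edges(self) -> Iterator[tuple[int, int]]:
        """Stored edges as index pairs; u < v for undirected graphs."""
        for u in range(self.n):
            for v in sorted(self._out[u]):
                if self.directed or u < v:
                    yield (u, v)

    def copy(self) -> "Graph":
        g = Graph(self.directed)
        g.node_labels = list(self.node_labels)
        g._label_to_index = dict(self._label_to_index)
        if self.directed:
            g._out = [set(s) for s in self._out]
            g._in = [set(s) for s in self._in]
        else:
            g._out = [set(s) for s in self._out]
            g._in = g._out
        g.edge_count = self.edge_count
        g.parent_index = list(self.parent_index) if self.parent_index else None
        return g

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "directed" if self.directed else "undirected"
        return f"<Graph {kind} n={self.n} m={self.edge_count}>"


def read_edge_list(source: IO[str] | str, directed: bool = False) -> Graph:
    """Parse a whitespace-separated edge list into a :class:`Graph`.

    ``source`` is an open text stream or a path.  Lines starting with ``#``
    or ``%`` and blank lines are skipped; tokens beyond the first two
    (weights, annotations) are ignored.  Self-loops are dropped with a
    warning; duplicate edges are collapsed.  Internal node index is the
    order of first appearance in the file.

    Raises
    ------
    EdgeListParseError
        On a line with a single token (with its line number) or when the
        input contains no edges at all.
    """
    close = False
    if isinstance(source, str):
        source = open(source, "r", encoding="utf-8")
        close = True
    g = Graph(directed)
    saw_edge_line = False
    try:
        for lineno, line in enumerate(source, start=1):
            stripped = line.strip()
            if not stripped or stripped[0] in "#%":
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise EdgeListParseError(f"line {lineno}: expected two endpoint labels, got {tokens!r}")
            saw_edge_line = True
            u, v = tokens[0], tokens[1]
            if u == v:
                g.add_node(u)
                logger.warning("line %d: dropping self-loop on node %r", lineno, u)
                continue
            g.add_edge(u, v)
    finally:
        if close:
            source.close()
    if not saw_edge_line:
        raise EdgeListParseError("empty edge list: no edge lines found")
    return g


def write_edge_list(g: Graph, dest: IO[str] | str) -> None:
    """Write one edge per line, endpoint labels separated by a tab."""
    close = False
    if isinstance(dest, str):
        dest = open(dest, "w", encoding="utf-8")
        close = True
    try:
        for u, v in g.edges():
            dest.write(f"{g.node_labels[u]}\t{g.node_labels[v]}\n")
    finally:
        if close:
            dest.close()


def induced_subgraph(g: Graph, nodes: Iterable[int]) -> Graph:
    """Subgraph on ``nodes`` with every edge of ``g`` between them.

    The result's ``parent_index`` maps each new index back to ``g``; node
    labels are carried over.  Sub-indices follow sorted parent indices.
    """
    node_list = sorted(set(nodes))
    for v in node_list:
        if not 0 <= v < g.n:
            raise IndexError(f"node index {v} not in graph of size {g.n}")
    sub = Graph(g.directed)
    pos = {v: i for i, v in enumerate(node_list)}
    for v in node_list:
        sub.add_node(g.node_labels[v])
    for v in node_list:
        for w in g._out[v]:
            if w in pos and (g.directed or v < w):
                sub._add_edge_idx(pos[v], pos[w])
    sub.parent_index = node_list
    return sub
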