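"""Canonical classification of small graph patterns.

A k-node pattern is identified by the minimum, over all k! vertex
permutations, of the row-major adjacency bitstring read as an integer
(k² bits, zero diagonal).  Under this convention the undirected 3-path is
pattern 78 (bits ``001 001 110``) and the triangle is pattern 238
(``011 101 110``) — the IDs used in FANMOD-style output.

Also provides exact counts of the pattern universe (connected
non-isomorphic graphs on k nodes) via the cycle index of the induced
action on vertex pairs and an inverse Euler transform; these serve as a
verification oracle for the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from math import factorial, gcd
from typing import Iterator, Sequence

from .esu import is_connected_subset
from .graph import Graph

__all__ = ["PatternID", "canonical_id", "classify", "count_patterns", "pattern_universe"]

MAX_CLASSIFY_K = 8   # k! canonicalization is the bottleneck; universe explodes beyond
MAX_COUNT_K = 10


@dataclass(frozen=True, order=True)
class PatternID:
    """Canonical identifier of a connected k-node pattern.

    ``value`` is the minimum row-major adjacency integer; ``edge_count`` is
    |E_m|, the number of edges of the pattern (arcs when directed).
    """

    value: int
    k: int
    directed: bool
    edge_count: int

    @property
    def bitstring(self) -> str:
        """Row-major adjacency bits of the canonical form, k² characters."""
        return format(self.value, f"0{self.k * self.k}b")

    def to_matrix(self) -> list[list[int]]:
        bits = self.bitstring
        k = self.k
        return [[int(bits[i * k + j]) for j in range(k)] for i in range(k)]

    def __str__(self) -> str:
        return str(self.value)


def _bits_from_matrix(adj: Sequence[Sequence[int]]) -> int:
    k = len(adj)
    value = 0
    for row in adj:
        for cell in row:
            value = (value << 1) | (1 if cell else 0)
    return value


@lru_cache(maxsize=None)
def _perm_bit_maps(k: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """For each permutation, the (source_bit, dest_bit) pairs of off-diagonal cells."""
    maps = []
    cells = [(i, j) for i in range(k) for j in range(k) if i != j]
    top = k * k - 1
    for perm in permutations(range(k)):
        pairs = tuple(
            (top - (i * k + j), top - (perm[i] * k + perm[j]))
            for i, j in cells
        )
        maps.append(pairs)
    return tuple(maps)


def _canonical_value(raw: int, k: int) -> int:
    best = raw
    for pairs in _perm_bit_maps(k):
        permuted = 0
        for src, dst in pairs:
            if raw >> src & 1:
                permuted |= 1 << dst
        if permuted < best:
            best = permuted
    return best


# raw (uncanonicalized) bitstring -> PatternID; the same few hundred raw
# matrices recur millions of times during enumeration.
_pattern_cache: dict[tuple[int, int, bool], PatternID] = {}


def _pattern_from_raw(raw: int, k: int, directed: bool) -> PatternID:
    key = (raw, k, directed)
    pid = _pattern_cache.get(key)
    if pid is None:
        ones = raw.bit_count()
        pid = PatternID(
            value=_canonical_value(raw, k),
            k=k,
            directed=directed,
            edge_count=ones if directed else ones // 2,
        )
        _pattern_cache[key] = pid
    return pid


def canonical_id(adj: Sequence[Sequence[int]], directed: bool) -> PatternID:
    """Canonical :class:`PatternID` of a k×k boolean adjacency matrix.

    The matrix must have a zero diagonal and, when ``directed`` is false,
    be symmetric.  Identical for any relabeling of the same pattern.
    """
    k = len(adj)
    if k > MAX_CLASSIFY_K:
        raise ValueError(f"classification supports k <= {MAX_CLASSIFY_K} (got {k})")
    for i in range(k):
        if len(adj[i]) != k:
            raise ValueError("adjacency matrix must be square")
        if adj[i][i]:
            raise ValueError(f"nonzero diagonal at position {i}: patterns are loop-free")
    if not directed:
        for i in range(k):
            for j in range(i + 1, k):
                if bool(adj[i][j]) != bool(adj[j][i]):
                    raise ValueError(f"asymmetric adjacency at ({i},{j}) with directed=False")
    return _pattern_from_raw(_bits_from_matrix(adj), k, directed)


def classify(g: Graph, nodes: Sequence[int]) -> PatternID:
    """Canonical pattern of the subgraph of ``g`` induced by ``nodes``.

    The induced adjacency is built in sorted internal-index order with arc
    directions preserved; the node set must induce a (weakly) connected
    subgraph.
    """
    ordered = sorted(set(nodes))
    k = len(ordered)
    if k > MAX_CLASSIFY_K:
        raise ValueError(f"classification supports k <= {MAX_CLASSIFY_K} (got {k})")
    if not is_connected_subset(g, tuple(ordered)):
        raise ValueError(f"node set {ordered} does not induce a connected subgraph")
    raw = 0
    for i in ordered:
        for j in ordered:
            raw = (raw << 1) | (1 if i != j and g.has_edge(i, j) else 0)
    return _pattern_from_raw(raw, k, g.directed)


# -- pattern universe counting (exact) --------------------------------


def _partitions(n: int, max_part: int | None = None) -> Iterator[tuple[int, ...]]:
    """Integer partitions of n as non-increasing tuples."""
    if max_part is None:
        max_part = n
    if n == 0:
        yield ()
        return
    for first in range(min(n, max_part), 0, -1):
        for rest in _partitions(n - first, first):
            yield (first,) + rest


def _unlabeled_graph_counts(n_max: int, directed: bool) -> list[int]:
    """Number of unlabeled simple (di)graphs on 0..n_max nodes.

    Burnside over S_n: for each cycle type, 2^(orbits of the induced action
    on vertex pairs), weighted by the number of permutations of that type.
    """
    counts = [1]
    for n in range(1, n_max + 1):
        total = 0
        for part in _partitions(n):
            mult: dict[int, int] = {}
            for p in part:
                mult[p] = mult.get(p, 0) + 1
            n_perms = factorial(n)
            for length, j in mult.items():
                n_perms //= length**j * factorial(j)
            if directed:
                # orbits on ordered distinct pairs
                orbits = sum(
                    ji * jj * gcd(li, lj)
                    for li, ji in mult.items()
                    for lj, jj in mult.items()
                ) - sum(mult.values())
            else:
                # orbits on unordered distinct pairs
                orbits = 0
                lengths = sorted(mult)
                for ai, li in enumerate(lengths):
                    ji = mult[li]
                    orbits += li * (ji * (ji - 1) // 2) + ji * (li // 2)
                    for lj in lengths[ai + 1:]:
                        orbits += ji * mult[lj] * gcd(li, lj)
            total += n_perms * (1 << orbits)
        counts.append(total // factorial(n))
    return counts


def _inverse_euler_transform(totals: list[int]) -> list[int]:
    """Connected counts c_n from total counts b_n (b_0 = 1 implied).

    Inverts  prod_n (1 - x^n)^(-c_n) = 1 + sum_n b_n x^n  in exact integers.
    """
    n_max = len(totals) - 1  # totals[0] == 1
    d = [0] * (n_max + 1)
    c = [0] * (n_max + 1)
    for n in range(1, n_max + 1):
        d[n] = n * totals[n] - sum(d[k] * totals[n - k] for k in range(1, n))
        divisor_sum = sum(dd * c[dd] for dd in range(1, n) if n % dd == 0)
        c[n], rem = divmod(d[n] - divisor_sum, n)
        assert rem == 0, "inverse Euler transform must be integral"
    return c


@lru_cache(maxsize=None)
def _connected_counts(directed: bool) -> tuple[int, ...]:
    totals = _unlabeled_graph_counts(MAX_COUNT_K, directed)
    return tuple(_inverse_euler_transform(totals))


def count_patterns(k: int, directed: bool) -> int:
    """Number of connected non-isomorphic simple (di)graphs on k nodes.

    Weak connectivity for digraphs.  Exact for 1 <= k <= 10 via Pólya
    counting of unlabeled graphs followed by an inverse Euler transform.
    """
    if not 1 <= k <= MAX_COUNT_K:
        raise ValueError(f"k must satisfy 1 <= k <= {MAX_COUNT_K} (got {k})")
    return _connected_counts(directed)[k]


def pattern_universe(k: int, directed: bool) -> set[int]:
    """Canonical IDs of every connected k-node pattern, by enumeration.

    Iterates all 2^(k²−k) adjacency matrices (upper-triangle only when
    undirected), keeps the weakly connected ones and canonicalizes.  A
    verification helper: cost is 2^bits · k!, so it is guarded to stay
    desk-scale (undirected k <= 5, directed k <= 4).
    """
    bits = k * (k - 1) // (1 if directed else 2)
    if (1 << bits) * factorial(k) > 5 * 10**6:
        raise ValueError(f"pattern universe enumeration too large for k={k}, directed={directed}")
    cells = [(i, j) for i in range(k) for j in range(i + 1, k)] if not directed else \
            [(i, j) for i in range(k) for j in range(k) if i != j]
    ids: set[int] = set()
    for mask in range(1 << bits):
        adj = [[0] * k for _ in range(k)]
        for b, (i, j) in enumerate(cells):
            if mask >> b & 1:
                adj[i][j] = 1
                if not directed:
                    adj[j][i] = 1
        if _matrix_connected(adj):
            ids.add(canonical_id(adj, directed).value)
    return ids


def _matrix_connected(adj: Sequence[Sequence[int]]) -> bool:
    k = len(adj)
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for u in range(k):
            if u not in seen and (adj[v][u] or adj[u][v]):
                seen.add(u)
                stack.append(u)
    return len(seen) == k
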