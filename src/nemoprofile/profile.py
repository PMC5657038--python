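"""SubgraphProfile construction, NemoProfile extraction and motif instance
collection (NemoCollect), with the AllCollect baseline.

The SubgraphProfile T is an n×m count matrix built in the same single ESU
pass that counts pattern frequencies: every emitted k-subgraph is
classified, and T[i, j] is incremented for each of its k nodes i under its
pattern column j.  T therefore stores the whole instance census in n×m
integers instead of f_G(j) node sets — the memory argument that makes
instance collection practical.

NemoProfile keeps only the columns of patterns judged to be motifs.
NemoCollect recovers the exact instance sets of a motif m from its column
alone: re-enumerate the subgraph induced by the nodes with a non-zero
entry in column m and keep the instances classifying to m.  Every
instance of m has all k nodes non-zero in column m, so nothing is lost;
re-classification discards any other pattern the induced subnetwork
contains, so nothing spurious is gained.  AllCollect — retaining every
instance during the full pass and filtering afterwards — is the
memory-heavy baseline and the correctness oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .esu import enumerate_subgraphs
from .graph import Graph, induced_subgraph
from .patterns import PatternID, classify

logger = logging.getLogger(__name__)

__all__ = [
    "Instance", "SubgraphProfile", "NemoProfile",
    "build_subgraph_profile", "extract_nemoprofile", "nemo_collect",
    "all_collect", "export_features", "write_profile", "write_instances",
]


@dataclass(frozen=True)
class Instance:
    """One concrete occurrence of a pattern: k node indices of the host graph."""

    nodes: frozenset[int]
    pattern: PatternID

    def sorted_nodes(self) -> tuple[int, ...]:
        return tuple(sorted(self.nodes))


class SubgraphProfile:
    """Node-by-pattern instance-count matrix T plus frequencies f_G.

    Columns are stored as sparse per-pattern maps {node: count}; n×m is
    small for k <= 5 but the dense matrix is only materialized on demand
    (:meth:`to_dense`).
    """

    def __init__(self, n_nodes: int, k: int, node_labels: Sequence[str]):
        self.n_nodes = n_nodes
        self.k = k
        self.node_labels = list(node_labels)
        self._columns: dict[PatternID, dict[int, int]] = {}
        self._freq: dict[PatternID, int] = {}

    def add_instance(self, nodes: Iterable[int], pattern: PatternID) -> None:
        col = self._columns.setdefault(pattern, {})
        self._freq[pattern] = self._freq.get(pattern, 0) + 1
        for v in nodes:
            col[v] = col.get(v, 0) + 1

    @property
    def pattern_index(self) -> list[PatternID]:
        """Patterns present in the graph, sorted by canonical value."""
        return sorted(self._columns)

    @property
    def frequencies(self) -> dict[PatternID, int]:
        """f_G: per-pattern instance counts."""
        return dict(self._freq)

    def frequency(self, pattern: PatternID) -> int:
        return self._freq.get(pattern, 0)

    def count(self, node: int, pattern: PatternID) -> int:
        """T[node, pattern]: instances of ``pattern`` containing ``node``."""
        return self._columns.get(pattern, {}).get(node, 0)

    def __getitem__(self, key: tuple[int, PatternID]) -> int:
        node, pattern = key
        return self.count(node, pattern)

    def column_support(self, pattern: PatternID) -> list[int]:
        """Sorted node indices with a non-zero entry in the pattern column."""
        return sorted(self._columns.get(pattern, {}))

    def to_dense(self) -> tuple[np.ndarray, list[PatternID]]:
        patterns = self.pattern_index
        dense = np.zeros((self.n_nodes, len(patterns)), dtype=np.int64)
        for j, pid in enumerate(patterns):
            for v, c in self._columns[pid].items():
                dense[v, j] = c
        return dense, patterns


@dataclass
class NemoProfile:
    """SubgraphProfile restricted to motif columns (dense, m is tiny)."""

    matrix: np.ndarray               # n × m_motifs integer counts
    patterns: list[PatternID]
    node_labels: list[str]
    k: int

    def column(self, pattern: PatternID) -> np.ndarray:
        return self.matrix[:, self.patterns.index(pattern)]

    def column_support(self, pattern: PatternID) -> list[int]:
        return list(np.flatnonzero(self.column(pattern)))


def build_subgraph_profile(g: Graph, k: int, collect_instances: bool = False):
    """Single ESU pass building T, f_G and optionally the raw instances.

    Returns the :class:`SubgraphProfile`, or ``(profile, instances)`` when
    ``collect_instances`` is true (AllCollect mode: the full per-instance
    (nodes, pattern) stream is retained).
    """
    sp = SubgraphProfile(g.n, k, g.node_labels)
    instances: list[Instance] = []
    for nodes in enumerate_subgraphs(g, k):
        pid = classify(g, nodes)
        sp.add_instance(nodes, pid)
        if collect_instances:
            instances.append(Instance(frozenset(nodes), pid))
    if collect_instances:
        return sp, instances
    return sp


def extract_nemoprofile(sp: SubgraphProfile, motifs: Iterable[PatternID]) -> NemoProfile:
    """Column subset of T for the motif patterns; row order unchanged."""
    motif_list = sorted(set(motifs))
    known = set(sp.pattern_index)
    for pid in motif_list:
        if pid not in known:
            raise KeyError(f"pattern {pid.value} is not a column of the SubgraphProfile")
    matrix = np.zeros((sp.n_nodes, len(motif_list)), dtype=np.int64)
    for j, pid in enumerate(motif_list):
        for v in sp.column_support(pid):
            matrix[v, j] = sp.count(v, pid)
    return NemoProfile(matrix=matrix, patterns=motif_list,
                       node_labels=sp.node_labels, k=sp.k)


def _sort_instances(g: Graph, instances: Iterable[Instance]) -> list[Instance]:
    # canonical report order: lexicographic on sorted original node labels
    return sorted(instances,
                  key=lambda inst: tuple(sorted(g.node_labels[v] for v in inst.nodes)))


def nemo_collect(g: Graph, profile: NemoProfile, motif: PatternID) -> list[Instance]:
    """Recover all instances of ``motif`` from its profile column.

    Re-enumerates only the subgraph of ``g`` induced by the non-zero nodes
    of the motif column, classifies each k-subgraph and keeps those whose
    pattern equals ``motif``, mapped back to the host graph's indices.
    """
    if motif not in profile.patterns:
        raise KeyError(f"pattern {motif.value} is not a column of the NemoProfile")
    support = profile.column_support(motif)
    k = profile.k
    if len(support) < k:
        return []
    sub = induced_subgraph(g, support)
    back = sub.parent_index
    found = []
    for nodes in enumerate_subgraphs(sub, k):
        if classify(sub, nodes) == motif:
            found.append(Instance(frozenset(back[v] for v in nodes), motif))
    return _sort_instances(g, found)


def all_collect(g: Graph, k: int, motifs: Iterable[PatternID]) -> dict[PatternID, list[Instance]]:
    """Baseline collection: keep every instance of the full pass, then
    filter to the motif patterns.  Semantically identical per-motif result
    to :func:`nemo_collect`; memory grows with the total instance count."""
    wanted = set(motifs)
    buckets: dict[PatternID, list[Instance]] = {pid: [] for pid in wanted}
    if not wanted:
        return buckets
    for nodes in enumerate_subgraphs(g, k):
        pid = classify(g, nodes)
        if pid in wanted:
            buckets[pid].append(Instance(frozenset(nodes), pid))
    return {pid: _sort_instances(g, lst) for pid, lst in buckets.items()}


def export_features(profile: NemoProfile, class_map: Mapping[str, str]) -> pd.DataFrame:
    """Attribute table for downstream classifiers (e.g. a decision tree).

    One row per node: node label, one integer column per motif (number of
    instances of that motif the node overlaps), and a final class column
    from ``class_map`` (missing labels get class ``unknown``, logged).
    """
    classes = []
    for label in profile.node_labels:
        if label in class_map:
            classes.append(class_map[label])
        else:
            logger.warning("node %r has no class label; using 'unknown'", label)
            classes.append("unknown")
    data: dict[str, object] = {"node": list(profile.node_labels)}
    for j, pid in enumerate(profile.patterns):
        data[f"motif_{pid.value}"] = profile.matrix[:, j]
    data["class"] = classes
    return pd.DataFrame(data)


def write_profile(profile: NemoProfile, dest: IO[str] | str) -> None:
    """Header row of motif IDs, then node label + tab-separated counts."""
    close = False
    if isinstance(dest, str):
        dest = open(dest, "w", encoding="utf-8")
        close = True
    try:
        dest.write("\t".join(["node"] + [str(pid.value) for pid in profile.patterns]) + "\n")
        for i, label in enumerate(profile.node_labels):
            row = [label] + [str(int(c)) for c in profile.matrix[i]]
            dest.write("\t".join(row) + "\n")
    finally:
        if close:
            dest.close()


def write_instances(g: Graph, instances: Sequence[Instance], dest: IO[str] | str) -> None:
    """One instance per line: motif ID then the k node labels, tab-separated."""
    close = False
    if isinstance(dest, str):
        dest = open(dest, "w", encoding="utf-8")
        close = True
    try:
        for inst in instances:
            labels = sorted(g.node_labels[v] for v in inst.nodes)
            dest.write(f"{inst.pattern.value}\t" + "\t".join(labels) + "\n")
    finally:
        if close:
            dest.close()
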