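"""Degree-preserving random-graph ensemble (switching null model).

Motif significance is judged against random graphs with the same degree
sequence as the input.  We use the standard switching model: repeated
double-edge swaps, Q attempts per edge (default 3), rejecting any swap that
would create a self-loop or a duplicate edge.  For digraphs a swap
exchanges arc heads, (a->b, c->d) -> (a->d, c->b), preserving every node's
in- and out-degree; the count of mutual arc pairs is not separately
conserved.

The whole ensemble is driven by one seed: replicate r draws its generator
from an independently spawned substream, so runs are bit-reproducible and
replicates are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .esu import enumerate_subgraphs
from .graph import Graph
from .patterns import PatternID, classify

__all__ = ["EnsembleConfig", "randomize", "count_frequencies", "ensemble_frequencies"]

DEFAULT_N_RANDOM = 100      # p-value resolution 0.01, matching the p < 0.01 rule
DEFAULT_SWAPS_PER_EDGE = 3


@dataclass(frozen=True)
class EnsembleConfig:
    """Random-ensemble settings: N replicates, Q attempted swaps per edge."""

    n_random: int = DEFAULT_N_RANDOM
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE
    seed: int = 0

    def __post_init__(self):
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if self.swaps_per_edge < 0:
            raise ValueError("swaps_per_edge must be >= 0")


def randomize(g: Graph, q: int, rng: np.random.Generator) -> Graph:
    """Degree-preserving randomization by q·|E| attempted double-edge swaps.

    Swaps creating self-loops or duplicate edges are rejected (the attempt
    is still consumed).  ``q=0`` returns a plain copy.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    out = g.copy()
    m = out.edge_count
    if m < 2 or q == 0:
        return out
    edges = list(out.edges())
    attempts = q * m
    choices = rng.integers(0, m, size=(attempts, 2))
    flips = rng.integers(0, 2, size=attempts)
    for t in range(attempts):
        i, j = int(choices[t, 0]), int(choices[t, 1])
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if not out.directed and flips[t]:
            c, d = d, c
        # proposed replacement: (a,d) and (c,b)
        if a == d or c == b:
            continue
        if len({a, b, c, d}) < 3:
            continue
        if out.has_edge(a, d) or out.has_edge(c, b):
            continue
        if not out.directed and (out.has_edge(d, a) or out.has_edge(b, c)):
            continue
        out._remove_edge_idx(a, b)
        out._remove_edge_idx(c, d)
        out._add_edge_idx(a, d)
        out._add_edge_idx(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
    return out


def count_frequencies(g: Graph, k: int) -> dict[PatternID, int]:
    """Per-pattern counts f(m) of connected induced k-subgraphs of ``g``."""
    freq: dict[PatternID, int] = {}
    for nodes in enumerate_subgraphs(g, k):
        pid = classify(g, nodes)
        freq[pid] = freq.get(pid, 0) + 1
    return freq


def ensemble_frequencies(g: Graph, k: int, cfg: EnsembleConfig,
                         patterns: set[PatternID] | None = None) -> dict[PatternID, list[int]]:
    """Pattern frequencies f_R(m) across N randomized replicates of ``g``.

    Returns one length-N list per pattern, covering every pattern seen in
    any replicate plus any requested ``patterns`` (typically those of the
    input graph); patterns absent from a replicate get frequency 0.  Fully
    reproducible from ``cfg.seed``.
    """
    n_random = cfg.n_random
    streams = np.random.SeedSequence(cfg.seed).spawn(n_random)
    freqs: dict[PatternID, list[int]] = {}
    if patterns:
        for pid in patterns:
            freqs[pid] = [0] * n_random
    for r in range(n_random):
        rg = randomize(g, cfg.swaps_per_edge, np.random.default_rng(streams[r]))
        for pid, count in count_frequencies(rg, k).items():
            if pid not in freqs:
                freqs[pid] = [0] * n_random
            freqs[pid][r] = count
    return freqs
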