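# Methods

## Model and pipeline

A network motif is a connected k-node induced subgraph pattern that occurs
in the input graph significantly more often than in random graphs with the
same degree sequence. The pipeline is the standard network-centric one:

1. **Enumeration (ESU).** Every connected induced k-subgraph is emitted
   exactly once. Each subgraph is anchored at its minimum-index node v; the
   extension set contains only nodes with index > v that neighbor the
   growing subgraph *exclusively* (not adjacent to any earlier-chosen
   node). Directed graphs are enumerated on the underlying undirected
   skeleton; arc directions matter only at classification. Candidates are
   consumed in ascending index order, so emission order is a pure function
   of the graph and k.
2. **Classification.** The induced adjacency matrix (sorted internal index
   order, directions preserved) is canonicalized as the minimum row-major
   bitstring integer over all k! vertex permutations. This brute-force
   canonical form is exact and cheap for k ≤ 8, the supported range; IDs
   are memoized by the raw (uncanonicalized) bitstring because the same few
   hundred raw matrices recur millions of times during enumeration. Under
   this convention the undirected 3-path is 78 and the triangle 238.
   Directed IDs use the same full k×k convention and are internally
   consistent, but are not guaranteed to match any other tool's directed
   numbering.
3. **Null model.** Degree-preserving switching: Q·|E| attempted double-edge
   swaps (default Q = 3), rejecting any swap that would create a self-loop
   or duplicate edge. Directed swaps exchange arc heads,
   (a→b, c→d) → (a→d, c→b), preserving all in/out degrees; the number of
   mutual arc pairs is *not* separately conserved. Default ensemble size
   N = 100 gives p-value resolution 0.01, matching the p < 0.01 rule. One
   seed drives the whole ensemble; replicate r uses an independently
   spawned substream, so results are bit-reproducible and independent of
   replicate order.
4. **Statistics.** Empirical p-value: fraction of replicates with
   f_R(m) ≥ f_G(m) (ties count). z-score: (f_G − mean(f_R)) / std(f_R) with
   the *population* (divide-by-N) standard deviation, the convention of the
   classic motif tools. When std = 0 (rigid degree sequences, e.g. a
   triangle) the z-score is undefined (NaN) rather than ±∞: the z-criterion
   simply cannot fire, while the p-criterion still can. Motif rule:
   f_G > 0 and (p < 0.01 or z > 2.0), strict inequalities, disjunctive.
   Patterns that appear only in random replicates are reported with
   f_G = 0, p = 1 and are never motifs. No multiple-testing correction is
   applied.

## SubgraphProfile, NemoProfile, NemoCollect

The SubgraphProfile T (n nodes × m patterns) is filled during the single
enumeration pass: each emitted instance increments T[i, j] for its k nodes
i under its pattern column j. Invariants maintained by construction and
checked by the tests: Σᵢ T[i, j] = k·f_G(j), and Σⱼ f_G(j) equals the total
subgraph census. Columns are stored as sparse per-pattern maps; the dense
matrix is materialized on demand (m is tiny for k ≤ 5).

NemoProfile is the column subset of T for the motif patterns. NemoCollect
recovers the instances of motif m from its column alone: take
S = {i : T[i, m] > 0}, re-enumerate the subgraph induced by S with the same
k, classify, and keep the instances whose pattern is m. Correctness: every
instance of m has all k nodes in S, so it survives restriction and is found
by the re-enumeration; conversely re-classification discards any other
pattern the induced subnetwork happens to contain. AllCollect (retain all
instances, filter afterwards) is kept as the oracle baseline, and the test
suite asserts per-pattern set equality of the two on random graphs.

One documented ambiguity: the column-selection rule for NemoCollect is
implemented as *non-zero* entries. Every entry of T is non-negative by
construction, so a non-negativity rule would select all nodes and collapse
NemoCollect into AllCollect; the non-zero reading is the one consistent
with the worked example's selected node set {1,2,3,8,9}.

Instances are reported as sorted original node labels, instance lists
sorted lexicographically, so outputs are diffable.

## Pattern-universe counting

`count_patterns(k, directed)` — the number of connected non-isomorphic
simple (di)graphs on k nodes — is the verification oracle for the
classifier. It is computed exactly for k ≤ 10 in integer arithmetic:
Burnside/Pólya over Sₖ cycle types gives the number of unlabeled graphs
(2^(orbits of the induced action on vertex pairs), ordered pairs for
digraphs), then an inverse Euler transform extracts the connected counts.
Tests additionally cross-check the classifier's distinct canonical IDs over
the enumerated universe against these counts (undirected k ≤ 5, directed
k ≤ 4 — enumeration costs 2^(k²−k)·k! canonicalizations, beyond which the
cross-check is not desk-scale; the counting formula itself is validated
against published tables through k = 10 undirected and k = 8 directed).

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | — (3–8) | motif size; k! canonicalization and the universe size bound it at 8 |
| N (`-r`) | 100 | random replicates; p-resolution is 1/N |
| Q (`--swaps-per-edge`) | 3 | attempted double-edge swaps per edge |
| p threshold | 0.01 | strict upper bound for the p-rule |
| z threshold | 2.0 | strict lower bound for the z-rule |
| seed | 0 | drives the whole ensemble deterministically |

`--force-motif ID` marks a pattern as a motif regardless of significance,
so the profile/collection path can be exercised deterministically on small
fixtures where nothing is genuinely significant.

## Synthetic data and what the tests show

The fixture catalogue provides a 9-node/10-edge worked-example graph
(size-3 census: 14 paths, 2 triangles sharing node 3 — its edge list is a
reconstruction consistent with all stated counts and instance sets;
uniqueness is not claimed), complete graphs, paths, stars, and a seeded
Erdős–Rényi generator used for property tests (n ≤ 40, k ∈ {3,4,5}, edge
probabilities 0.1–0.5). These exercise every contract — exact-once
enumeration, profile conservation, NemoCollect ≡ AllCollect, degree
preservation — at sizes where brute-force oracles are feasible. They do not
emulate the heavy-tailed degree distributions or the scale (10³–10⁴ nodes,
millions of subgraphs) of real PPI networks, so passing tests certify
correctness of the algorithms, not wall-clock performance or the
statistical power of motif detection on real data.

## Numerical and degenerate-input choices

* Self-loops in input edge lists are dropped with a warning (standard for
  motif analysis); duplicate edges collapse; extra columns are ignored.
* Empty ensembles and out-of-range k raise errors rather than returning
  sentinels.
* Swap attempts on graphs with fewer than two edges are no-ops; q = 0
  returns an exact copy, which the tests use to pin the degenerate
  statistics (p = 1, z undefined, zero motifs).
* All counting is exact integer arithmetic; the only floats are the
  ensemble statistics.

## Known limitations

* Classification is brute-force over k! permutations — fine for k ≤ 8, not
  a nauty replacement.
* The directed null model does not conserve mutual-arc counts; analyses
  sensitive to reciprocity should interpret directed z-scores accordingly.
* No sampling variant of the enumerator and no parallelism.
* No multiple-testing correction across patterns.
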