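# nemoprofile

Network motif detection for biological networks — with the part most motif
finders leave out: the actual motif *instances*.

Given a network such as a protein–protein interaction (PPI) graph,
`nemoprofile` enumerates every connected induced k-node subgraph exactly
once (the ESU algorithm), classifies each into a canonical pattern, and
tests each pattern's frequency against a degree-preserving random ensemble.
A pattern m is a **network motif** when

```
p(m) = (1/N) Σₙ [ f_R(m) ≥ f_G(m) ]  <  0.01      or
z(m) = (f_G(m) − mean(f_R(m))) / std(f_R(m))  >  2.0
```

where f_G(m) is the pattern's count in the input graph and f_R(m) its count
in each of the N randomized replicates.

The distinctive piece is the **SubgraphProfile**: an n×m matrix T, built in
the *same* single enumeration pass, where T[i, j] counts how many instances
of pattern j contain node i. Storing the instance census this way instead
of as explicit node sets removes the memory blow-up that normally makes
instance collection impractical. From T:

* **NemoProfile** — the motif columns of T, directly usable as per-node
  features (e.g. for essential-protein prediction with a decision tree);
* **NemoCollect** — exact recovery of every instance of a motif m by
  re-enumerating only the small subgraph induced by the nodes with a
  non-zero entry in column m;
* **NemoCount** — the classic frequency + significance report, with no
  profile kept at all.

`AllCollect` (keep every instance during the full pass, filter afterwards)
is included as the memory-heavy baseline; per motif it returns exactly the
same instance sets as NemoCollect, and the test suite checks that
equivalence on random graphs.

## Worked example

The package ships a 9-node, 10-edge fixture graph (`fixtures.fixture_f9`)
whose size-3 census is 14 path-type instances (pattern 78) and 2 triangles
(pattern 238: nodes {1,2,3} and {3,8,9}). Pattern IDs are the minimum
row-major adjacency bitstring over all vertex permutations — `078` is the
3-path (`001001110`), `238` the triangle (`011101110`).

```
$ python -c "from nemoprofile.fixtures import fixture_f9
from nemoprofile.graph import write_edge_list
write_edge_list(fixture_f9(), 'f9.txt')"
$ nemoprofile f9.txt -k 3 --mode nemocollect -r 100 --seed 1 --force-motif 238 -o demo -v
INFO n=9 |E_G|=10 k=3 total_subgraphs=16 patterns=2 motifs=1 N=100 seed=1
INFO wrote demo.counts.tsv
INFO wrote demo.profile.tsv
INFO wrote demo.motif238.instances.tsv
```

`demo.counts.tsv` — frequency and significance per pattern (16 subgraphs
total; on a graph this small the triangle is not statistically significant,
hence `--force-motif 238` to exercise the collection path):

```
pattern_id  adjacency  f_G  mean_fR  std_fR    z_score    p_value  is_motif
78          001001110  14   15.83    2.47004   -0.740879  0.94     0
238         011101110  2    1.39     0.823347  0.740879   0.49     1
```

`demo.profile.tsv` — the profile column for pattern 238: node 3 sits in
both triangles (entry 2), nodes 1, 2, 8, 9 in one each, all others in none:

```
node  238
1     1
2     1
3     2
...
```

`demo.motif238.instances.tsv` — NemoCollect re-enumerates only the
subgraph induced by the five non-zero nodes {1,2,3,8,9} and recovers
exactly the two triangle instances:

```
238  1  2  3
238  3  8  9
```

The same pipeline is available as a library (`read_edge_list`,
`build_subgraph_profile`, `find_motifs`, `extract_nemoprofile`,
`nemo_collect`, `export_features` for classifier-ready feature tables).

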