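import io

import numpy as np
import pytest

from nemoprofile import (all_collect, build_subgraph_profile, classify,
                         enumerate_subgraphs, export_features,
                         extract_nemoprofile, nemo_collect, write_instances,
                         write_profile)
from nemoprofile.fixtures import complete_graph, random_graph
from nemoprofile.patterns import canonical_id

TRI = canonical_id([[0, 1, 1], [1, 0, 1], [1, 1, 0]], directed=False)
PATH = canonical_id([[0, 1, 0], [1, 0, 1], [0, 1, 0]], directed=False)


def _labels(g, instance):
    return tuple(sorted(g.node_labels[v] for v in instance.nodes))


class TestSubgraphProfile:
    def test_f9_frequencies(self, f9):
        sp = build_subgraph_profile(f9, 3)
        assert sp.frequency(PATH) == 14
        assert sp.frequency(TRI) == 2
        assert sum(sp.frequencies.values()) == 16

    def test_f9_node3_in_both_triangles(self, f9):
        sp = build_subgraph_profile(f9, 3)
        assert sp[f9.index_of("3"), TRI] == 2

    def test_f9_triangle_column_support(self, f9):
        sp = build_subgraph_profile(f9, 3)
        support = {f9.node_labels[v] for v in sp.column_support(TRI)}
        assert support == {"1", "2", "3", "8", "9"}

    def test_k3_profile_is_all_ones(self, triangle):
        sp = build_subgraph_profile(triangle, 3)
        dense, patterns = sp.to_dense()
        assert patterns == [TRI]
        assert dense.shape == (3, 1)
        assert (dense == 1).all()

    @pytest.mark.parametrize("seed,k", [(0, 3), (1, 3), (2, 4), (3, 4)])
    def test_conservation_invariants(self, seed, k):
        """Column sums are k*f_G(j); frequencies sum to the total census."""
        g = random_graph(18, 0.25, seed=seed)
        sp = build_subgraph_profile(g, k)
        dense, patterns = sp.to_dense()
        for j, pid in enumerate(patterns):
            assert dense[:, j].sum() == k * sp.frequency(pid)
        total = sum(1 for _ in enumerate_subgraphs(g, k))
        assert sum(sp.frequencies.values()) == total

    def test_frequencies_match_brute_force_counts(self, f9):
        from collections import Counter
        from nemoprofile import brute_force_enumerate
        sp = build_subgraph_profile(f9, 3)
        oracle = Counter(classify(f9, s) for s in brute_force_enumerate(f9, 3))
        assert sp.frequencies == dict(oracle)


class TestExtractNemoProfile:
    def test_motif_column_subset(self, f9):
        sp = build_subgraph_profile(f9, 3)
        nprof = extract_nemoprofile(sp, {TRI})
        assert nprof.patterns == [TRI]
        assert {f9.node_labels[v] for v in nprof.column_support(TRI)} == {"1", "2", "3", "8", "9"}

    def test_all_patterns_equals_full_profile(self, f9):
        sp = build_subgraph_profile(f9, 3)
        nprof = extract_nemoprofile(sp, sp.pattern_index)
        dense, patterns = sp.to_dense()
        assert nprof.patterns == patterns
        assert (nprof.matrix == dense).all()

    def test_empty_motif_set(self, f9):
        sp = build_subgraph_profile(f9, 3)
        nprof = extract_nemoprofile(sp, set())
        assert nprof.matrix.shape == (9, 0)

    def test_unknown_motif_raises(self, triangle):
        sp = build_subgraph_profile(triangle, 3)
        with pytest.raises(KeyError):
            extract_nemoprofile(sp, {PATH})


class TestNemoCollect:
    def test_f9_triangle_instances(self, f9):
        sp = build_subgraph_profile(f9, 3)
        nprof = extract_nemoprofile(sp, {TRI})
        found = {_labels(f9, inst) for inst in nemo_collect(f9, nprof, TRI)}
        assert found == {("1", "2", "3"), ("3", "8", "9")}

    def test_k3_whole_graph(self, triangle):
        sp = build_subgraph_profile(triangle, 3)
        nprof = extract_nemoprofile(sp, {TRI})
        (inst,) = nemo_collect(triangle, nprof, TRI)
        assert inst.nodes == frozenset({0, 1, 2})

    def test_f9_path_matches_allcollect(self, f9):
        sp = build_subgraph_profile(f9, 3)
        nprof = extract_nemoprofile(sp, {PATH})
        nemo = nemo_collect(f9, nprof, PATH)
        assert len(nemo) == 14
        assert nemo == all_collect(f9, 3, {PATH})[PATH]

    def test_unknown_motif_raises(self, f9):
        sp = build_subgraph_profile(f9, 3)
        nprof = extract_nemoprofile(sp, {TRI})
        with pytest.raises(KeyError):
            nemo_collect(f9, nprof, PATH)

    @pytest.mark.parametrize("seed,k", [(s, k) for s in range(6) for k in (3, 4)])
    def test_equivalence_with_allcollect_on_random_graphs(self, seed, k):
        """NemoCollect recovers exactly the AllCollect instance sets, per pattern."""
        g = random_graph(25, 0.15, seed=100 + seed)
        sp = build_subgraph_profile(g, k)
        patterns = sp.pattern_index
        if not patterns:
            return
        nprof = extract_nemoprofile(sp, patterns)
        baseline = all_collect(g, k, patterns)
        for pid in patterns:
            assert nemo_collect(g, nprof, pid) == baseline[pid]


class TestAllCollect:
    def test_f9_both_patterns_total_sixteen(self, f9):
        buckets = all_collect(f9, 3, {PATH, TRI})
        assert len(buckets[PATH]) + len(buckets[TRI]) == 16

    def test_empty_motif_set(self, f9):
        assert all_collect(f9, 3, set()) == {}


class TestExportAndWriters:
    def test_feature_table_f9(self, f9):
        sp = build_subgraph_profile(f9, 3)
        nprof = extract_nemoprofile(sp, {TRI})
        table = export_features(nprof, {"3": "essential"})
        assert list(table.columns) == ["node", "motif_238", "class"]
        assert len(table) == 9
        row3 = table[table["node"] == "3"].iloc[0]
        assert row3["motif_238"] == 2 and row3["class"] == "essential"
        assert (table[table["node"] != "3"]["class"] == "unknown").all()

    def test_feature_table_empty_motifs(self, f9):
        sp = build_subgraph_profile(f9, 3)
        nprof = extract_nemoprofile(sp, set())
        table = export_features(nprof, {})
        assert list(table.columns) == ["node", "class"]

    def test_feature_table_k3_symmetric(self, triangle):
        sp = build_subgraph_profile(triangle, 3)
        nprof = extract_nemoprofile(sp, {TRI})
        table = export_features(nprof, {l: "x" for l in triangle.node_labels})
        assert (table["motif_238"] == 1).all()

    def test_profile_writer(self, f9):
        sp = build_subgraph_profile(f9, 3)
        nprof = extract_nemoprofile(sp, {TRI})
        buf = io.StringIO()
        write_profile(nprof, buf)
        lines = buf.getvalue().splitlines()
        assert lines[0] == "node\t238"
        assert len(lines) == 10
        assert "3\t2" in lines

    def test_instance_writer_sorted_labels(self, f9):
        sp = build_subgraph_profile(f9, 3)
        nprof = extract_nemoprofile(sp, {TRI})
        buf = io.StringIO()
        write_instances(f9, nemo_collect(f9, nprof, TRI), buf)
        assert buf.getvalue() == "238\t1\t2\t3\n238\t3\t8\t9\n"
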