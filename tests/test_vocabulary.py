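"""Vocabulary construction: similarity graph, MCL, token assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import reference_mcl_partition
from phalife.vocabulary import (SPECIAL_TOKENS, AlignmentFormatError,
                                EmptyVocabularyWarning, ProteinCluster,
                                ProteinVocabulary, SimilarityEdge,
                                build_similarity_graph, build_vocabulary,
                                markov_cluster, read_alignment_table)


def edge(q, s, e, bits=100.0):
    return SimilarityEdge(q, s, e, bits)


class TestSimilarityGraph:
    def test_bidirectional_pair_keeps_strongest_weight(self):
        g = build_similarity_graph([edge("A", "B", 1e-50),
                                    edge("B", "A", 1e-40)])
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["weight"] == pytest.approx(50.0)

    def test_self_alignment_contributes_node_but_no_edge(self):
        g = build_similarity_graph([edge("A", "A", 0.0)])
        assert set(g.nodes) == {"A"}
        assert g.number_of_edges() == 0

    def test_disjoint_triangles_preserved(self):
        edges = [edge(a, b, 1e-10) for a, b in
                 [("A", "B"), ("B", "C"), ("A", "C"),
                  ("D", "E"), ("E", "F"), ("D", "F")]]
        g = build_similarity_graph(edges)
        assert g.number_of_nodes() == 6
        assert g.number_of_edges() == 6
        assert all(d["weight"] == pytest.approx(10.0)
                   for _, _, d in g.edges(data=True))

    def test_cutoff_drops_weak_alignments(self):
        g = build_similarity_graph([edge("A", "B", 1e-3)], evalue_cutoff=1e-5)
        assert g.number_of_nodes() == 0

    def test_extreme_evalue_floored(self):
        g = build_similarity_graph([edge("A", "B", 0.0)])
        assert g["A"]["B"]["weight"] == pytest.approx(200.0)

    def test_empty_input_gives_empty_graph(self):
        g = build_similarity_graph([])
        assert g.number_of_nodes() == 0

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "aln.tsv"
        path.write_text("A\tB\t90\t100\t5\t0\t1\t100\t1\t100\t1e-50\t200\n"
                        "A\tB\tbroken\n")
        with pytest.raises(AlignmentFormatError, match="line 2"):
            list(read_alignment_table(path))

    def test_gzip_and_plain_inputs_agree(self, tmp_path):
        import gzip
        row = "A\tB\t90\t100\t5\t0\t1\t100\t1\t100\t1e-50\t200.5\n"
        (tmp_path / "a.tsv").write_text(row)
        with gzip.open(tmp_path / "a.tsv.gz", "wt") as fh:
            fh.write(row)
        plain = list(read_alignment_table(tmp_path / "a.tsv"))
        zipped = list(read_alignment_table(tmp_path / "a.tsv.gz"))
        assert plain == zipped == [SimilarityEdge("A", "B", 1e-50, 200.5)]


def _graph_from_matrix(weights, names):
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(names)
    n = len(names)
    for i in range(n):
        for j in range(i + 1, n):
            if weights[i, j] > 0:
                g.add_edge(names[i], names[j], weight=weights[i, j])
    return g


class TestMarkovCluster:
    def test_disjoint_triangles_give_two_clusters(self):
        edges = [edge(a, b, 1e-10) for a, b in
                 [("A", "B"), ("B", "C"), ("A", "C"),
                  ("D", "E"), ("E", "F"), ("D", "F")]]
        clusters = markov_cluster(build_similarity_graph(edges))
        assert sorted(sorted(c.members) for c in clusters) == [
            ["A", "B", "C"], ["D", "E", "F"]]

    def test_empty_graph_gives_empty_list(self):
        import networkx as nx
        assert markov_cluster(nx.Graph()) == []

    def test_isolated_node_is_singleton(self):
        g = build_similarity_graph([edge("A", "A", 0.0),
                                    edge("B", "C", 1e-20)])
        clusters = markov_cluster(g)
        assert {frozenset(c.members) for c in clusters} == {
            frozenset({"A"}), frozenset({"B", "C"})}

    def test_barbell_matches_reference_implementation(self):
        # two strong triangles joined by one weak bridge edge
        names = list("ABCDEFG")
        w = np.zeros((7, 7))
        for i, j in [(0, 1), (1, 2), (0, 2), (4, 5), (5, 6), (4, 6)]:
            w[i, j] = w[j, i] = 50.0
        w[3, 2] = w[2, 3] = 50.0   # D hangs off triangle ABC
        w[3, 4] = w[4, 3] = 5.0    # weak bridge to triangle EFG
        ours = markov_cluster(_graph_from_matrix(w, names), inflation=2.0,
                              self_loop_weight=1.0)
        expected = reference_mcl_partition(w, inflation=2.0, self_loop=1.0)
        got = {frozenset(names.index(m) for m in c.members) for c in ours}
        assert got == expected

    @pytest.mark.parametrize("inflation", [1.5, 2.0, 4.0])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_small_random_graphs_match_reference(self, inflation, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        w = np.triu(rng.random((n, n)) * 20 * (rng.random((n, n)) < 0.5), 1)
        w = w + w.T
        names = [chr(65 + i) for i in range(n)]
        ours = markov_cluster(_graph_from_matrix(w, names),
                              inflation=inflation, self_loop_weight=1.0)
        expected = reference_mcl_partition(w, inflation=inflation,
                                           self_loop=1.0)
        got = {frozenset(names.index(m) for m in c.members) for c in ours}
        assert got == expected

    def test_output_is_a_partition(self, universe):
        g = build_similarity_graph(universe.alignment_edges())
        clusters = markov_cluster(g)
        members = [m for c in clusters for m in c.members]
        assert len(members) == len(set(members)) == g.number_of_nodes()

    def test_invariant_to_uniform_weight_scaling(self):
        rng = np.random.default_rng(7)
        w = np.triu(rng.random((6, 6)) * 10, 1)
        w = w + w.T
        names = list("ABCDEF")
        a = markov_cluster(_graph_from_matrix(w, names), self_loop_weight=1.0)
        # scale self-loops identically so the stochastic matrix is unchanged
        b = markov_cluster(_graph_from_matrix(w * 100, names),
                           self_loop_weight=100.0)
        assert {frozenset(c.members) for c in a} == \
               {frozenset(c.members) for c in b}

    def test_rejects_inflation_at_or_below_one(self):
        import networkx as nx
        with pytest.raises(ValueError, match="inflation"):
            markov_cluster(nx.Graph(), inflation=1.0)


class TestBuildVocabulary:
    def c(self, cid, *members):
        return ProteinCluster.from_members(cid, members)

    def test_singleton_removed(self):
        v = build_vocabulary([self.c(0, "A", "B"), self.c(1, "C")])
        assert v.size == 6

    def test_size_tie_broken_by_smallest_member(self):
        v = build_vocabulary([self.c(0, "C", "D"), self.c(1, "A", "B"),
                              self.c(2, "E")])
        assert v.token_for_cluster(1) == 5   # {A,B} first
        assert v.token_for_cluster(0) == 6
        assert v.size == 7

    def test_all_singletons_warns_and_keeps_specials_only(self):
        with pytest.warns(EmptyVocabularyWarning):
            v = build_vocabulary([self.c(0, "A")])
        assert v.size == len(SPECIAL_TOKENS) == 5

    def test_order_independent(self):
        clusters = [self.c(0, "A", "B"), self.c(1, "C", "D", "E"),
                    self.c(2, "F"), self.c(3, "G", "H")]
        v1 = build_vocabulary(clusters)
        v2 = build_vocabulary(clusters[::-1])
        assert [c.members for c in v1.clusters] == \
               [c.members for c in v2.clusters]
        assert v1.size == v2.size

    def test_token_cluster_roundtrip(self):
        v = build_vocabulary([self.c(4, "A", "B"), self.c(9, "C", "D")])
        for t in v.cluster_token_ids:
            assert v.token_for_cluster(v.cluster_for_token(t)) == t

    def test_representative_is_smallest_member(self):
        v = build_vocabulary([self.c(0, "Z", "M", "A")])
        assert v.clusters[0].representative_id == "A"

    def test_save_load_roundtrip(self, tmp_path, universe, vocab):
        prefix = tmp_path / "toy"
        vocab.save(prefix, params={"inflation": 2.0})
        loaded = ProteinVocabulary.load(prefix)
        assert loaded.size == vocab.size
        assert [c.members for c in loaded.clusters] == \
               [c.members for c in vocab.clusters]
        assert (tmp_path / "toy.vocab.json").exists()


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.permutations(list(range(6))))
def test_vocabulary_identical_under_any_cluster_permutation(perm):
    base = [ProteinCluster.from_members(i, [f"p{i}a", f"p{i}b"])
            for i in range(6)]
    v1 = build_vocabulary(base)
    v2 = build_vocabulary([base[i] for i in perm])
    assert [c.members for c in v1.clusters] == [c.members for c in v2.clusters]
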