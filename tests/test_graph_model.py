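"""Graph model: graphID codec, canonical labeling, isomorphism, connectivity."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifcensus import (
    DirectedGraph,
    GraphSizeError,
    MalformedGraphIDError,
    canonical_id_bruteforce,
    decode_graph_id,
    graph_id,
    is_isomorphic,
    is_weakly_connected,
)
from motifcensus.graph_model import relabel_graph_id

from conftest import random_k_digraph


def complete_digraph(n):
    return DirectedGraph(n, [(u, v) for u in range(n) for v in range(n) if u != v])


class TestDirectedGraphInvariants:
    def test_rejects_self_loops(self):
        with pytest.raises(ValueError):
            DirectedGraph(3, [(1, 1)])

    def test_deduplicates_parallel_arcs(self):
        g = DirectedGraph(3, [(0, 1), (0, 1)])
        assert g.n_arcs == 1

    def test_rejects_out_of_range_vertices(self):
        with pytest.raises(ValueError):
            DirectedGraph(2, [(0, 2)])

    def test_reciprocal_pair_is_two_arcs(self):
        g = DirectedGraph(2, [(0, 1), (1, 0)])
        assert g.n_arcs == 2 and g.has_arc(0, 1) and g.has_arc(1, 0)


class TestGraphIDCodec:
    @pytest.mark.parametrize("arcs, expected", [
        ([(1, 0), (2, 0), (2, 1)], 38),     # feed-forward loop
        ([], 0),                             # empty matrix
        ([(u, v) for u in range(3) for v in range(3) if u != v], 238),  # 011101110
    ])
    def test_three_node_encodings(self, arcs, expected):
        assert graph_id(DirectedGraph(3, arcs)) == expected

    def test_decode_feed_forward_loop(self):
        g = decode_graph_id(38, 3)
        assert g.arcs == {(1, 0), (2, 0), (2, 1)}

    def test_decode_empty_four_node(self):
        g = decode_graph_id(0, 4)
        assert g.n_nodes == 4 and g.n_arcs == 0

    def test_explicit_vertex_order_changes_encoding(self):
        g = DirectedGraph(3, [(1, 0), (2, 0), (2, 1)])
        assert graph_id(g, order=(2, 1, 0)) != graph_id(g)

    def test_size_guard(self):
        with pytest.raises(GraphSizeError):
            graph_id(DirectedGraph(7))

    def test_diagonal_bit_rejected(self):
        with pytest.raises(MalformedGraphIDError):
            decode_graph_id(1 << 8, 3)  # entry (1,1) of a 3-node matrix

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(min_value=3, max_value=6), st.randoms(use_true_random=False))
    def test_roundtrip_random_digraphs(self, k, rnd):
        g = DirectedGraph(k)
        for u in range(k):
            for v in range(k):
                if u != v and rnd.random() < 0.4:
                    g.add_arc(u, v)
        assert decode_graph_id(graph_id(g), k) == g


class TestCanonicalBruteforce:
    def test_all_relabelings_of_ffl_canonicalize_to_38(self):
        for perm in itertools.permutations(range(3)):
            gid = relabel_graph_id(38, 3, perm)
            assert canonical_id_bruteforce(gid, 3) == 38

    def test_single_arc_class(self):
        # lowest legal off-diagonal bit corresponds to matrix entry (3,2)
        assert canonical_id_bruteforce(graph_id(DirectedGraph(3, [(0, 1)])), 3) == 2

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_automorphism_full_classes(self, k):
        assert canonical_id_bruteforce(0, k) == 0
        full = graph_id(complete_digraph(k))
        assert canonical_id_bruteforce(full, k) == full

    @settings(derandomize=True, max_examples=150)
    @given(st.integers(min_value=3, max_value=5), st.randoms(use_true_random=False))
    def test_invariant_under_relabeling_and_minimal(self, k, rnd):
        g = random_k_digraph(k, rnd)
        gid = graph_id(g)
        canon = canonical_id_bruteforce(gid, k)
        assert canon <= gid
        perm = list(range(k))
        rnd.shuffle(perm)
        assert canonical_id_bruteforce(relabel_graph_id(gid, k, perm), k) == canon
        assert canonical_id_bruteforce(canon, k) == canon  # idempotent


class TestIsomorphism:
    def test_relabelings_are_isomorphic(self, ffl):
        assert is_isomorphic(ffl, decode_graph_id(relabel_graph_id(38, 3, (2, 0, 1)), 3))

    def test_path_vs_fan(self):
        path = DirectedGraph(3, [(0, 1), (1, 2)])
        fan = DirectedGraph(3, [(0, 1), (0, 2)])
        assert not is_isomorphic(path, fan)

    def test_node_count_mismatch_is_false(self):
        assert not is_isomorphic(DirectedGraph(3), DirectedGraph(4))

    def test_agrees_with_canonical_equality_on_all_3node_pairs(self):
        # exhaustive: all 64 x 64 pairs of loop-free 3-node digraphs
        ids = [g for g in range(512) if not any((g >> (8 - 4 * i)) & 1 for i in range(3))]
        assert len(ids) == 64
        canon = {gid: canonical_id_bruteforce(gid, 3) for gid in ids}
        graphs = {gid: decode_graph_id(gid, 3) for gid in ids}
        for g1 in ids:
            for g2 in ids:
                assert is_isomorphic(graphs[g1], graphs[g2]) == (canon[g1] == canon[g2])

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(min_value=4, max_value=6), st.randoms(use_true_random=False))
    def test_agrees_with_canonical_equality_sampled(self, k, rnd):
        g1, g2 = random_k_digraph(k, rnd), random_k_digraph(k, rnd)
        expected = canonical_id_bruteforce(graph_id(g1), k) == canonical_id_bruteforce(graph_id(g2), k)
        assert is_isomorphic(g1, g2) == expected

    def test_agrees_with_networkx_oracle(self):
        # independent third-party cross-check on random same-degree pairs
        import networkx as nx
        import random
        rnd = random.Random(5)
        for trial in range(60):
            k = rnd.randint(4, 6)
            g1 = random_k_digraph(k, rnd)
            if trial % 2:  # make isomorphic cases common, not vanishing
                perm = list(range(k))
                rnd.shuffle(perm)
                g2 = DirectedGraph(k, [(perm[u], perm[v]) for (u, v) in g1.iter_arcs()])
            else:
                g2 = random_k_digraph(k, rnd)
            n1 = nx.DiGraph(list(g1.arcs))
            n1.add_nodes_from(range(k))
            n2 = nx.DiGraph(list(g2.arcs))
            n2.add_nodes_from(range(k))
            assert is_isomorphic(g1, g2) == nx.is_isomorphic(n1, n2)


class TestWeakConnectivity:
    def test_ffl_connected(self, ffl):
        assert is_weakly_connected(ffl)

    def test_isolated_vertices_disconnect(self):
        assert not is_weakly_connected(DirectedGraph(4, [(0, 1)]))

    def test_single_node_connected(self):
        assert is_weakly_connected(DirectedGraph(1))

    def test_direction_is_ignored(self):
        assert is_weakly_connected(DirectedGraph(3, [(0, 1), (2, 1)]))
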