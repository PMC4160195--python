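"""SN-set decomposition, contraction, and the reticulation-leaf criteria."""

import itertools
import random

import networkx as nx
import pytest

from tripnet import (
    Triplet,
    TripletSet,
    aho_graph,
    build_triplet_digraph,
    contract,
    criterion_I,
    criterion_II,
    criterion_III,
    feedback_arc_removal,
    height_from_digraph,
    is_sn_set,
    random_binary_tree,
    reticulation_candidates,
    select_reticulation,
    sn_decompose,
)
from tripnet.digraph import pair
from tripnet.sn import remove_max_weight_edges
from tripnet.trees import build_tree, triplets_of_tree


def fig8_heights(fig8):
    return height_from_digraph(feedback_arc_removal(build_triplet_digraph(fig8)))


def weights_of(h, labels):
    return {p: h(*p) for p in itertools.combinations(sorted(labels), 2)}


class TestIsSnSet:
    def test_published_block(self, fig8):
        assert is_sn_set({"n", "o"}, fig8)

    def test_singletons_always_qualify(self, fig8):
        for x in sorted(fig8.labels):
            assert is_sn_set({x}, fig8)

    def test_published_non_block(self, fig8):
        # lo|k witnesses: o outside, l and k inside
        assert not is_sn_set({"k", "l"}, fig8)


class TestRemoveMaxWeightEdges:
    def test_removes_only_the_top_class(self):
        edges = {pair("a", "b"): 1, pair("a", "c"): 1, pair("b", "c"): 2}
        remaining, w = remove_max_weight_edges(edges)
        assert w == 2 and set(remaining) == {pair("a", "b"), pair("a", "c")}

    def test_uniform_weights_empty_the_graph(self):
        edges = {pair("a", "b"): 3, pair("a", "c"): 3}
        remaining, w = remove_max_weight_edges(edges)
        assert w == 3 and remaining == {}

    def test_edgeless_input_is_an_error(self):
        with pytest.raises(ValueError):
            remove_max_weight_edges({})


class TestSnDecompose:
    def test_published_partition(self, fig8):
        h = fig8_heights(fig8)
        parts = sn_decompose(fig8.labels, weights_of(h, fig8.labels), fig8)
        assert parts == [
            frozenset("i"), frozenset("j"), frozenset("k"),
            frozenset("l"), frozenset("m"), frozenset({"n", "o"}),
        ]

    def test_first_split_weights_match_walkthrough(self, fig8):
        # removing the weight-6 then weight-5 classes separates {n,o} and {m}
        h = fig8_heights(fig8)
        edges = weights_of(h, fig8.labels)
        edges, w1 = remove_max_weight_edges(edges)
        edges, w2 = remove_max_weight_edges(edges)
        assert (w1, w2) == (6, 5)
        g = nx.Graph()
        g.add_nodes_from(fig8.labels)
        g.add_edges_from(edges)
        comps = {frozenset(c) for c in nx.connected_components(g)}
        assert frozenset({"n", "o"}) in comps and frozenset({"m"}) in comps

    def test_tree_consistent_input_matches_aho_components(self):
        for seed in range(5):
            t = random_binary_tree(6, seed=seed)
            ts = triplets_of_tree(t)
            g = build_triplet_digraph(ts)
            h = height_from_digraph(g)
            parts = sn_decompose(ts.labels, weights_of(h, ts.labels), ts)
            aho = {
                frozenset(c)
                for c in nx.connected_components(aho_graph(ts, ts.labels))
            }
            assert set(parts) == aho

    def test_two_taxa_give_singletons(self):
        parts = sn_decompose("ab", {pair("a", "b"): 1}, TripletSet())
        assert parts == [frozenset("a"), frozenset("b")]

    def test_blocks_are_sn_sets_and_partition(self, fig8):
        h = fig8_heights(fig8)
        parts = sn_decompose(fig8.labels, weights_of(h, fig8.labels), fig8)
        union = frozenset().union(*parts)
        assert union == fig8.labels
        assert sum(len(p) for p in parts) == len(union)
        assert all(is_sn_set(p, fig8) for p in parts)


class TestContract:
    def test_all_singletons_is_isomorphic_to_input(self, fig4):
        h = height_from_digraph(build_triplet_digraph(fig4))
        parts = [frozenset([x]) for x in sorted(fig4.labels)]
        inst = contract(parts, fig4, h)
        assert set(inst.nodes) == fig4.labels
        assert inst.tau == fig4
        assert all(inst.w[p] == h(*p) for p in inst.w)

    def test_published_contraction_weights(self, fig8):
        h = fig8_heights(fig8)
        parts = sn_decompose(fig8.labels, weights_of(h, fig8.labels), fig8)
        inst = contract(parts, fig8, h)
        assert set(inst.nodes) == {"i", "j", "k", "l", "m", "n+o"}
        assert inst.w[pair("k", "l")] == 1
        assert inst.w[pair("l", "n+o")] == 5  # min(h(l,n)=6, h(l,o)=5)
        assert inst.w[pair("m", "n+o")] == 5
        assert inst.w[pair("i", "n+o")] == 6
        # triplets with two labels in one block vanish: no|m and no|k
        assert len(inst.tau) == 13

    def test_single_block_gives_empty_triplets(self, fig2):
        h = height_from_digraph(build_triplet_digraph(fig2))
        inst = contract([frozenset(fig2.labels)], fig2, h)
        assert len(inst.tau) == 0


class TestCriteria:
    def fig8_instance(self, fig8):
        h = fig8_heights(fig8)
        parts = sn_decompose(fig8.labels, weights_of(h, fig8.labels), fig8)
        return contract(parts, fig8, h), h

    def test_published_cascade(self, fig8):
        inst, h = self.fig8_instance(fig8)
        r1 = criterion_I(inst, h)
        assert r1 == ["k", "l"]
        r2 = criterion_II(inst, r1)
        assert r2 == ["k", "l"]
        r3 = criterion_III(inst, r2)
        assert r3 == ["l"]

    def test_singleton_stages_short_circuit(self, fig8):
        inst, h = self.fig8_instance(fig8)
        assert criterion_II(inst, ["k"]) == ["k"]
        assert criterion_III(inst, ["k"]) == ["k"]

    def test_total_tie_keeps_all_blocks(self):
        # a perfectly symmetric instance: every block ties through criterion I
        ts = TripletSet()
        h_vals = {pair(a, b): 1 for a, b in itertools.combinations("abc", 2)}
        from tripnet.digraph import HeightFunction

        h = HeightFunction(h_vals, 1)
        inst = contract([frozenset(x) for x in "abc"], ts, h)
        r1 = criterion_I(inst, h)
        assert r1 == ["a", "b", "c"]
        assert criterion_II(inst, r1) == ["a", "b", "c"]
        assert criterion_III(inst, criterion_II(inst, r1)) == ["a", "b", "c"]


class TestSelection:
    def test_published_choice_and_tree_consistency_after(self, fig8):
        h = fig8_heights(fig8)
        parts = sn_decompose(fig8.labels, weights_of(h, fig8.labels), fig8)
        inst = contract(parts, fig8, h)
        chosen, reduced = select_reticulation(inst, h, speed="slow")
        assert chosen == "l"
        assert "l" not in reduced.nodes
        assert all("l" not in t.labels for t in reduced.tau)
        assert build_tree(reduced.tau, labels=reduced.nodes) is not None

    def test_fast_mode_is_seed_deterministic(self, fig8):
        h = fig8_heights(fig8)
        parts = sn_decompose(fig8.labels, weights_of(h, fig8.labels), fig8)
        inst = contract(parts, fig8, h)
        a = reticulation_candidates(inst, h, "fast", random.Random(4))
        b = reticulation_candidates(inst, h, "fast", random.Random(4))
        assert a == b

    def test_selection_strictly_shrinks_instance(self, fig8):
        h = fig8_heights(fig8)
        parts = sn_decompose(fig8.labels, weights_of(h, fig8.labels), fig8)
        inst = contract(parts, fig8, h)
        _, reduced = select_reticulation(inst, h)
        assert len(reduced.nodes) == len(inst.nodes) - 1


class TestContractedSingletonProperty:
    def test_contracted_instance_redecomposes_to_singletons(self, fig8):
        h = fig8_heights(fig8)
        parts = sn_decompose(fig8.labels, weights_of(h, fig8.labels), fig8)
        inst = contract(parts, fig8, h)
        again = sn_decompose(inst.nodes, inst.w, inst.tau)
        assert all(len(p) == 1 for p in again)

    def test_on_random_tree_consistent_inputs(self):
        for seed in range(5):
            t = random_binary_tree(7, seed=seed)
            ts = triplets_of_tree(t)
            h = height_from_digraph(build_triplet_digraph(ts))
            parts = sn_decompose(ts.labels, weights_of(h, ts.labels), ts)
            inst = contract(parts, ts, h)
            again = sn_decompose(inst.nodes, inst.w, inst.tau)
            assert all(len(p) == 1 for p in again)
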