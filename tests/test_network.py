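"""Network validity, level, heights, consistency, and serialisation."""

import itertools

import networkx as nx
import pytest

from tripnet import (
    PhyloNetwork,
    Triplet,
    TripletSet,
    build_tree,
    consistent_triplet_set,
    from_enewick,
    isomorphic,
    network_from_height,
    network_height_function,
    network_level,
    random_binary_tree,
    random_network,
    read_edge_list,
    reticulation_count,
    to_enewick,
    tree_height_function,
    triplet_consistent,
    validate_network,
    write_edge_list,
)
from tripnet.digraph import HeightFunction, pair
from tripnet.trees import read_newick, triplets_of_tree

from conftest import CONVERSE_WITNESS_ENEWICK, SAME_HEIGHT_NETWORK, SAME_HEIGHT_TREE
from _oracles import consistency_oracle


def net_of(newick):
    return from_enewick(newick)


class TestValidate:
    def test_binary_tree_is_valid(self):
        n = PhyloNetwork.from_tree(random_binary_tree(5, seed=0))
        assert validate_network(n) == []

    def test_bad_degree_reported(self):
        g = nx.DiGraph([(0, 1), (0, 2), (1, 3), (2, 3), (3, "a"), (3, "b"),
                        (1, "c"), (2, "d")])
        n = PhyloNetwork(g, 0)
        assert any("degrees (2, 2)" in v for v in validate_network(n))

    def test_cycle_reported(self):
        g = nx.DiGraph([(0, 1), (1, 2), (2, 1), (1, "a"), (0, "b")])
        n = PhyloNetwork(g, 0)
        assert any("cycle" in v for v in validate_network(n))


class TestCountsAndLevel:
    def test_tree_is_level_zero(self):
        n = PhyloNetwork.from_tree(random_binary_tree(4, seed=1))
        assert reticulation_count(n) == 0 and network_level(n) == 0

    def test_one_blob(self):
        n = net_of("((a,(b)#H1),(#H1,c));")
        assert reticulation_count(n) == 1 and network_level(n) == 1

    def test_two_independent_blobs_are_level_one(self):
        n = net_of("(((a,(b)#H1),(#H1,c)),((d,(e)#H2),(#H2,f)));")
        assert validate_network(n) == []
        assert reticulation_count(n) == 2
        assert network_level(n) == 1

    def test_level_bounded_by_reticulation_count(self):
        for seed in range(6):
            n = random_network(6, 2, seed=seed)
            assert network_level(n) <= reticulation_count(n)

    def test_invalid_network_rejected(self):
        g = nx.DiGraph([(0, 1), (1, 2), (2, 1), (1, "a"), (0, "b")])
        with pytest.raises(ValueError):
            network_level(PhyloNetwork(g, 0))


class TestNetworkHeights:
    def test_tree_case_matches_tree_heights(self):
        t = random_binary_tree(6, seed=2)
        hn = network_height_function(PhyloNetwork.from_tree(t)).h
        assert hn.values == tree_height_function(t).values

    def test_network_and_tree_can_share_heights(self):
        # a 1-reticulation network and a tree with identical height functions
        net = net_of(SAME_HEIGHT_NETWORK)
        tree = read_newick(SAME_HEIGHT_TREE)
        assert reticulation_count(net) == 1
        assert network_height_function(net).h.values == tree_height_function(tree).values

    def test_consistent_triplet_can_lack_strict_inequality(self):
        # frozen witness: ij|k consistent although no height inequality holds
        net = net_of(CONVERSE_WITNESS_ENEWICK)
        assert validate_network(net) == []
        h = network_height_function(net).h
        tr = Triplet("i", "j", "k")
        assert not (h("i", "j") < h("i", "k") or h("i", "j") < h("j", "k"))
        assert consistency_oracle(net, tr)
        assert triplet_consistent(net, tr)


class TestTripletConsistency:
    def test_tree_cases(self):
        n = PhyloNetwork.from_tree(read_newick("((i,j),k);"))
        assert triplet_consistent(n, Triplet("i", "j", "k"))
        assert not triplet_consistent(n, Triplet("j", "k", "i"))

    def test_missing_label_is_an_error(self):
        n = PhyloNetwork.from_tree(read_newick("((i,j),k);"))
        with pytest.raises(ValueError):
            triplet_consistent(n, Triplet("i", "j", "z"))

    def test_matches_oracle_on_random_networks(self):
        checked = 0
        for seed in range(10):
            n = random_network(5, seed % 3, seed=seed)
            for x, y, z in itertools.combinations(sorted(n.leaves), 3):
                for tr in (Triplet(x, y, z), Triplet(x, z, y), Triplet(y, z, x)):
                    assert triplet_consistent(n, tr) == consistency_oracle(n, tr)
                    checked += 1
        assert checked > 200

    def test_height_inequality_implies_consistency(self):
        # the sufficient direction, spot-checked against the oracle
        for seed in range(8):
            n = random_network(5, 1 + seed % 2, seed=seed)
            h = n.height.h
            for x, y, z in itertools.combinations(sorted(n.leaves), 3):
                for tr in (Triplet(x, y, z), Triplet(x, z, y), Triplet(y, z, x)):
                    a, b = tr.cherry
                    k = tr.outgroup
                    if h(a, b) < h(a, k) or h(a, b) < h(b, k):
                        assert consistency_oracle(n, tr)


class TestConsistentTripletSet:
    def test_contains_build_example_inputs(self, fig2):
        t = build_tree(fig2)
        ts = consistent_triplet_set(PhyloNetwork.from_tree(t))
        assert set(fig2) <= set(ts)

    def test_three_leaf_tree_has_one_triplet(self):
        n = PhyloNetwork.from_tree(read_newick("((i,j),k);"))
        assert len(consistent_triplet_set(n)) == 1

    def test_binary_tree_set_is_dense_and_rebuilds_tree(self):
        t = random_binary_tree(6, seed=5)
        ts = consistent_triplet_set(PhyloNetwork.from_tree(t))
        assert ts.is_dense()
        assert build_tree(ts) == t


class TestNetworkFromHeight:
    def test_raw_construction_shifts_heights_by_one(self):
        for seed in range(3):
            t = random_binary_tree(5, seed=seed)
            h = tree_height_function(t)
            raw = network_from_height(h, t.leaves, normalize=False)
            hn = network_height_function(raw).h
            assert all(hn(*p) == v + 1 for p, v in h.values.items())

    def test_normalized_network_is_valid(self):
        t = read_newick("(((j,k),i),l);")
        h = tree_height_function(t)
        n = network_from_height(h, t.leaves)
        assert validate_network(n) == []

    def test_constant_heights_give_valid_network(self):
        h = HeightFunction({pair(a, b): 2 for a, b in itertools.combinations("abc", 2)}, 2)
        n = network_from_height(h, "abc")
        assert validate_network(n) == []
        assert n.leaves == {"a", "b", "c"}

    def test_two_taxa_give_cherry(self):
        h = HeightFunction({pair("a", "b"): 1}, 1)
        n = network_from_height(h, "ab")
        assert validate_network(n) == []
        assert reticulation_count(n) == 0 and n.leaves == {"a", "b"}


class TestENewick:
    def test_tree_serialises_as_plain_newick(self):
        t = random_binary_tree(5, seed=1)
        s = to_enewick(PhyloNetwork.from_tree(t))
        assert "#" not in s
        assert read_newick(s) == t

    def test_single_reticulation_tag_appears_twice(self):
        n = random_network(4, 1, seed=2)
        s = to_enewick(n)
        assert s.count("#H1") == 2

    def test_round_trip_is_isomorphic(self):
        for seed in range(8):
            n = random_network(6, seed % 4, seed=seed)
            assert isomorphic(n, from_enewick(to_enewick(n)))

    def test_malformed_input_rejected(self):
        with pytest.raises(ValueError):
            from_enewick("((a,b)#X;")

    def test_edge_list_round_trip(self):
        n = random_network(5, 2, seed=3)
        assert isomorphic(n, read_edge_list(write_edge_list(n)))
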