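"""Shared fixtures: the published worked examples and constructed witnesses."""

from __future__ import annotations

import pytest

from tripnet import TripletSet

# BUILD worked example: {bc|a, ac|d, de|b}
FIG2_TRIPLETS = [("b", "c", "a"), ("a", "c", "d"), ("d", "e", "b")]

# HBUILD worked example: {kl|j, kl|i, jk|i, jl|i}
FIG4_TRIPLETS = [("k", "l", "j"), ("k", "l", "i"), ("j", "k", "i"), ("j", "l", "i")]

# level-1 worked example on {i..o}; consistent with a 1-reticulation network,
# not with any tree
FIG8_TRIPLETS = [
    ("i", "j", "l"), ("j", "k", "i"), ("k", "l", "j"), ("k", "l", "i"),
    ("n", "o", "m"), ("l", "o", "k"), ("j", "l", "o"), ("m", "n", "l"),
    ("m", "n", "j"), ("n", "o", "k"), ("m", "o", "i"), ("j", "k", "n"),
    ("i", "k", "m"), ("i", "j", "o"), ("i", "l", "n"),
]

# full-pipeline worked example on {i..n}
FIG9_TRIPLETS = [
    ("j", "k", "i"), ("l", "i", "j"), ("m", "j", "i"), ("j", "n", "i"),
    ("k", "l", "i"), ("i", "k", "m"), ("i", "k", "n"), ("l", "m", "i"),
    ("l", "n", "i"), ("m", "n", "i"), ("k", "l", "j"), ("k", "m", "j"),
    ("j", "n", "k"), ("l", "m", "j"), ("j", "l", "n"), ("m", "n", "j"),
    ("k", "l", "m"), ("k", "l", "n"), ("m", "n", "k"), ("m", "n", "l"),
]

# Synthetic witness (found by seeded search, frozen): a level-1 network in
# which ij|k is consistent although h(i,j) is not strictly below h(i,k) or
# h(j,k) — the converse of the height-inequality criterion fails.
CONVERSE_WITNESS_ENEWICK = "(x,(((i,#H1),j),(k)#H1));"

# Synthetic witness (found by seeded search, frozen): a 1-reticulation
# network and a tree sharing the same height function.
SAME_HEIGHT_NETWORK = "((t1,((t2,t3),#H1)),(t4)#H1);"
SAME_HEIGHT_TREE = "(t1,((t2,t3),t4));"


@pytest.fixture
def fig2():
    return TripletSet.from_tuples(FIG2_TRIPLETS)


@pytest.fixture
def fig4():
    return TripletSet.from_tuples(FIG4_TRIPLETS)


@pytest.fixture
def fig8():
    return TripletSet.from_tuples(FIG8_TRIPLETS)


@pytest.fixture
def fig9():
    return TripletSet.from_tuples(FIG9_TRIPLETS)
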