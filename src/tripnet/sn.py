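"""SN-set decomposition and reticulation-leaf selection.

An SN-set of a triplet set tau is a taxon subset ``S`` with no triplet
``ij|k`` having the cherry member ``i`` outside ``S`` while ``j`` and ``k``
lie inside: nothing outside "reaches into" ``S``.  SN-sets are the units
that can be contracted to single nodes without losing structure.  Where
dense-input algorithms find maximal SN-sets through density, here the height
function stands in: repeatedly deleting the maximum-weight edge class of the
height-weighted complete graph splits off components, and components that
are SN-sets become blocks (non-SN components are decomposed further).

When the contracted instance admits no tree, one node must become a
reticulation leaf.  Three nested criteria rank the candidates: (I) smallest
minimum — then smallest maximum — height of edges leaving the block's leaf
set; (II) largest degree in the subgraph of globally minimal-weight
contracted edges; (III) deleting the candidate (and its triplets) should
split the rest into as many nontrivial SN-sets as possible.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .digraph import HeightFunction, Pair, pair
from .triplets import Triplet, TripletSet

__all__ = [
    "ContractedInstance",
    "is_sn_set",
    "remove_max_weight_edges",
    "sn_decompose",
    "contract",
    "criterion_I",
    "criterion_II",
    "criterion_III",
    "reticulation_candidates",
    "select_reticulation",
]


def is_sn_set(s: Iterable[str], ts: TripletSet) -> bool:
    """No triplet has one cherry member outside ``s`` with the other cherry
    member and the outgroup inside."""
    inside = frozenset(s)
    for t in ts:
        a, b = t.cherry
        c = t.outgroup
        if c not in inside:
            continue
        if (a in inside) != (b in inside):
            return False
    return True


def _components(vertices: frozenset, edges: dict) -> list[frozenset]:
    g = nx.Graph()
    g.add_nodes_from(vertices)
    g.add_edges_from(p for p in edges)
    return [frozenset(c) for c in nx.connected_components(g)]


def remove_max_weight_edges(edges: dict[Pair, int]) -> tuple[dict[Pair, int], int]:
    """Drop the entire maximum-weight edge class; return (remaining, weight)."""
    if not edges:
        raise ValueError("cannot remove edges from an edgeless graph")
    wmax = max(edges.values())
    return {p: w for p, w in edges.items() if w < wmax}, wmax


def sn_decompose(
    vertices: Iterable[str], weights: dict[Pair, int], ts: TripletSet
) -> list[frozenset[str]]:
    """Partition ``vertices`` into SN-sets of ``ts``, guided by ``weights``.

    ``weights`` must cover every pair of ``vertices`` (a complete graph).
    Within each connected component, maximum-weight edge classes are removed
    until the component splits; split-off components that are SN-sets become
    blocks, the others are decomposed further.  Blocks are returned sorted
    by smallest member.
    """
    verts = frozenset(vertices)
    edges = {
        pair(a, b): weights[pair(a, b)]
        for a, b in itertools.combinations(sorted(verts), 2)
    }
    blocks: list[frozenset[str]] = []
    stack: list[tuple[frozenset, dict]] = [(verts, edges)]
    while stack:
        v, e = stack.pop()
        if len(v) == 1:
            blocks.append(v)
            continue
        comps = _components(v, e)
        while len(comps) == 1:
            e, _ = remove_max_weight_edges(e)
            comps = _components(v, e)
        for comp in comps:
            ec = {p: w for p, w in e.items() if p[0] in comp and p[1] in comp}
            if len(comp) == 1 or is_sn_set(comp, ts):
                blocks.append(comp)
            else:
                stack.append((comp, ec))
    return sorted(blocks, key=min)


def block_name(members: Iterable[str]) -> str:
    m = sorted(members)
    return m[0] if len(m) == 1 else "+".join(m)


@dataclass
class ContractedInstance:
    """The contracted problem: SN-blocks as nodes, induced triplets and
    minimum-height weights between blocks.

    ``w(s_i, s_j) = min{ h(x, y) : x in S_i, y in S_j }``; ``tau_S``
    contains ``s_i s_j | s_k`` iff some ``xy|z`` of the original set has its
    labels spread over the three distinct blocks.  Triplets with two labels
    in one block contribute nothing (their signal lives inside the block).
    """

    blocks: dict[str, frozenset[str]]
    tau: TripletSet
    w: dict[Pair, int]

    @property
    def nodes(self) -> list[str]:
        return sorted(self.blocks)

    @property
    def surviving_leaves(self) -> frozenset[str]:
        return frozenset().union(*self.blocks.values())

    def remove(self, name: str) -> "ContractedInstance":
        """Delete a block, its triplets and its edges."""
        blocks = {k: v for k, v in self.blocks.items() if k != name}
        w = {p: v for p, v in self.w.items() if name not in p}
        return ContractedInstance(blocks, self.tau.without_label(name), w)


def contract(
    partition: Sequence[frozenset[str]], ts: TripletSet, h: HeightFunction
) -> ContractedInstance:
    blocks = {block_name(b): frozenset(b) for b in partition}
    to_block: dict[str, str] = {}
    for name, members in blocks.items():
        for x in members:
            to_block[x] = name
    tau = []
    for t in ts:
        a, b = t.cherry
        c = t.outgroup
        na, nb, nc = to_block[a], to_block[b], to_block[c]
        if len({na, nb, nc}) == 3:
            tau.append(Triplet(na, nb, nc))
    w = {}
    for n1, n2 in itertools.combinations(sorted(blocks), 2):
        w[pair(n1, n2)] = min(
            h(x, y) for x in blocks[n1] for y in blocks[n2]
        )
    return ContractedInstance(blocks, TripletSet(tau), w)


def criterion_I(inst: ContractedInstance, leaf_h: HeightFunction) -> list[str]:
    """Blocks with minimal ``m_i`` (min leaf-level height of edges leaving
    the block), ties broken by minimal ``M_i`` (the max such height).

    Heights are read off the original leaf-level function restricted to
    surviving taxa, not the contracted weights.
    """
    if len(inst.blocks) < 2:
        raise ValueError("criterion I needs at least 2 blocks")
    alive = inst.surviving_leaves
    stats: dict[str, tuple[int, int]] = {}
    for name, members in inst.blocks.items():
        out = [
            leaf_h(x, y) for x in members for y in alive - members
        ]
        if not out:  # pendant block with no outside edges: not a candidate
            continue
        stats[name] = (min(out), max(out))
    best_m = min(v[0] for v in stats.values())
    tied = {k: v for k, v in stats.items() if v[0] == best_m}
    best_mm = min(v[1] for v in tied.values())
    return sorted(k for k, v in tied.items() if v[1] == best_mm)


def criterion_II(inst: ContractedInstance, r1: Sequence[str]) -> list[str]:
    """Members of R1 with maximum degree in the subgraph induced by the
    globally minimum-weight contracted edges."""
    if not r1:
        raise ValueError("criterion II needs a nonempty R1")
    if len(r1) == 1:
        return list(r1)
    wmin = min(inst.w.values())
    deg: dict[str, int] = {s: 0 for s in inst.nodes}
    for (a, b), v in inst.w.items():
        if v == wmin:
            deg[a] += 1
            deg[b] += 1
    best = max(deg[s] for s in r1)
    return sorted(s for s in r1 if deg[s] == best)


def criterion_III(inst: ContractedInstance, r2: Sequence[str]) -> list[str]:
    """Members of R2 whose deletion splits the contracted instance into the
    most SN-sets with more than one (contracted) node."""
    if not r2:
        raise ValueError("criterion III needs a nonempty R2")
    if len(r2) == 1:
        return list(r2)
    n_s: dict[str, int] = {}
    for s in r2:
        reduced = inst.remove(s)
        parts = sn_decompose(reduced.nodes, reduced.w, reduced.tau)
        n_s[s] = sum(1 for p in parts if len(p) > 1)
    best = max(n_s.values())
    return sorted(s for s in r2 if n_s[s] == best)


def reticulation_candidates(
    inst: ContractedInstance,
    leaf_h: HeightFunction,
    speed: str = "slow",
    rng: random.Random | None = None,
) -> list[str]:
    """Candidate reticulation leaves after the I -> II -> III cascade.

    The cascade short-circuits as soon as a stage is a singleton.  When R3
    still holds several blocks the speed mode decides how many branches the
    caller examines: ``slow`` all of them, ``normal`` two seeded-random
    picks, ``fast`` one.
    """
    r1 = criterion_I(inst, leaf_h)
    if len(r1) == 1:
        return r1
    r2 = criterion_II(inst, r1)
    if len(r2) == 1:
        return r2
    r3 = criterion_III(inst, r2)
    if len(r3) == 1 or speed == "slow":
        return r3
    rng = rng or random.Random(0)
    if speed == "normal":
        return sorted(rng.sample(r3, min(2, len(r3))))
    if speed == "fast":
        return [rng.choice(r3)]
    raise ValueError(f"unknown speed mode {speed!r}")


def select_reticulation(
    inst: ContractedInstance,
    leaf_h: HeightFunction,
    speed: str = "slow",
    rng: random.Random | None = None,
) -> tuple[str, ContractedInstance]:
    """Pick one reticulation leaf (first candidate) and return the reduced
    instance.  Callers wanting the full branch set use
    :func:`reticulation_candidates`."""
    cands = reticulation_candidates(inst, leaf_h, speed, rng)
    chosen = cands[0]
    return chosen, inst.remove(chosen)
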