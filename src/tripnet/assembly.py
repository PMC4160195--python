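"""End-to-end assembly: from an arbitrary triplet set to a consistent network.

The pipeline, in order: (1) layer the pair digraph into a height function,
removing feedback arcs first if the triplets conflict; (2) try HBUILD — a
success yields a binarized tree and only the patching step remains; (3-5)
otherwise decompose the taxa into SN-sets, contract them, and repeatedly
delete criterion-selected reticulation leaves until the contracted triplets
admit a tree; (6) re-insert the deleted leaves in reverse order, each below
a fresh reticulation node spanning the edge pair that keeps the most
contracted triplets consistent; (7-8) recurse into multi-taxon SN-blocks and
graft their networks in place of the contracted leaves; (9) patch any
remaining inconsistent triplets by extra reticulation edges between the
pendant edges of the most-offended cherry pair, until every input triplet is
consistent.  The reticulation count is heuristically small, never proven
minimal.
"""

from __future__ import annotations

import itertools
import random
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .digraph import (
    build_triplet_digraph,
    feedback_arc_removal,
    height_from_digraph,
    pair,
)
from .network import (
    PhyloNetwork,
    network_level,
    reticulation_count,
    triplet_consistent,
    validate_network,
)
from .sn import ContractedInstance, contract, reticulation_candidates, sn_decompose
from .trees import RootedTree, binarize, build_tree, hbuild
from .triplets import Triplet, TripletSet

__all__ = [
    "TripNetResult",
    "tripnet",
    "insert_reticulation_leaves",
    "patch_inconsistent",
    "recurse_and_expand",
]


@dataclass
class TripNetResult:
    """A constructed network plus how it was obtained.

    ``contracted_instances`` records every contracted SN-instance the run
    (including nested recursions) created; each re-decomposes into singleton
    SN-sets, which diagnostics and tests can verify.
    """

    network: PhyloNetwork
    reticulation_order: list[str]
    log: list[str] = field(default_factory=list)
    contracted_instances: list[ContractedInstance] = field(default_factory=list)

    @property
    def n_reticulations(self) -> int:
        return reticulation_count(self.network)

    @property
    def level(self) -> int:
        return network_level(self.network)


def _fresh_int(g: nx.DiGraph) -> "itertools.count":
    start = max((n for n in g.nodes if isinstance(n, int)), default=-1) + 1
    return itertools.count(start)


def _edge_order(g: nx.DiGraph, root) -> list[tuple]:
    """Deterministic edge enumeration: DFS preorder with children sorted by
    smallest descendant leaf label."""
    mind: dict = {}
    for v in reversed(list(nx.topological_sort(g))):
        kids = list(g.successors(v))
        mind[v] = str(v) if not kids else min(mind[c] for c in kids)
    index: dict = {}
    stack = [root]
    seen = set()
    while stack:
        v = stack.pop()
        if v in seen:
            continue
        seen.add(v)
        index[v] = len(index)
        for c in sorted(g.successors(v), key=lambda c: (mind[c], str(c)), reverse=True):
            stack.append(c)
    return sorted(g.edges, key=lambda e: (index[e[0]], index[e[1]]))


def insert_reticulation_leaves(
    t: RootedTree, leaves: Sequence[str], ts_context: TripletSet
) -> PhyloNetwork:
    """Hang each deleted leaf below a new reticulation node (reverse order).

    For each leaf, every unordered pair of distinct current edges is tried:
    both edges are subdivided, the two new nodes feed a fresh reticulation
    node whose single child is the leaf.  The pair keeping the most
    ``ts_context`` triplets (those whose labels are all present) consistent
    wins; ties go to the first pair in the deterministic edge order.
    """
    if not t.is_binary():
        raise ValueError("reticulation leaves are inserted into a binary tree")
    g = t.graph.copy()
    root = t.root
    ids = _fresh_int(g)
    for x in reversed(list(leaves)):
        if x in g.nodes:
            raise ValueError(f"leaf {x!r} already present")
        present = {n for n in g.nodes if g.out_degree(n) == 0} | {x}
        relevant = [tr for tr in ts_context if tr.labels <= present]
        edges = _edge_order(g, root)
        best: tuple[int, PhyloNetwork] | None = None
        for e1, e2 in itertools.combinations(edges, 2):
            cand = g.copy()
            y1, y2, y3 = next(ids), next(ids), next(ids)
            for (a, b), y in ((e1, y1), (e2, y2)):
                cand.remove_edge(a, b)
                cand.add_edge(a, y)
                cand.add_edge(y, b)
            cand.add_edge(y1, y3)
            cand.add_edge(y2, y3)
            cand.add_edge(y3, x)
            net = PhyloNetwork(cand, root)
            score = sum(1 for tr in relevant if triplet_consistent(net, tr))
            if best is None or score > best[0]:
                best = (score, net)
                if score == len(relevant):
                    break
        if best is None:
            raise ValueError("tree has fewer than two edges; cannot insert")
        g = best[1].graph
    return PhyloNetwork(g, root)


def patch_inconsistent(n: PhyloNetwork, ts: TripletSet) -> PhyloNetwork:
    """Add reticulation edges until every triplet of ``ts`` is consistent.

    Each round groups the still-inconsistent triplets by cherry pair, takes
    the pair ``{i, j}`` offending most (ties lexicographic), subdivides the
    two pendant edges and joins the new nodes by an arc (tail on the
    lexicographically smaller leaf's edge; reversed if that orientation
    leaves some of the pair's triplets inconsistent).  Every round fixes the
    selected group, so the inconsistent set strictly shrinks.
    """
    if not n.leaves >= ts.labels:
        raise ValueError("network must cover the triplet labels")
    current = n
    n_bad_before = None
    while True:
        bad = [tr for tr in ts if not triplet_consistent(current, tr)]
        if not bad:
            return current
        if n_bad_before is not None and len(bad) >= n_bad_before:
            raise RuntimeError("patching failed to make progress")
        n_bad_before = len(bad)
        groups: dict[tuple[str, str], int] = {}
        for tr in bad:
            groups[tr.cherry] = groups.get(tr.cherry, 0) + 1
        top = max(groups.values())
        i, j = min(c for c, v in groups.items() if v == top)
        group = [tr for tr in bad if tr.cherry == (i, j)]

        def attach(tail_leaf: str, head_leaf: str) -> PhyloNetwork:
            g = current.graph.copy()
            ids = _fresh_int(g)
            nodes = {}
            for leaf in (tail_leaf, head_leaf):
                (p,) = g.predecessors(leaf)
                v = next(ids)
                g.remove_edge(p, leaf)
                g.add_edge(p, v)
                g.add_edge(v, leaf)
                nodes[leaf] = v
            g.add_edge(nodes[tail_leaf], nodes[head_leaf])
            return PhyloNetwork(g, current.root)

        forward = attach(i, j)
        if all(triplet_consistent(forward, tr) for tr in group):
            current = forward
            continue
        backward = attach(j, i)
        fwd_bad = sum(1 for tr in group if not triplet_consistent(forward, tr))
        bwd_bad = sum(1 for tr in group if not triplet_consistent(backward, tr))
        current = backward if bwd_bad < fwd_bad else forward


def _cherry_network(a: str, b: str) -> PhyloNetwork:
    g = nx.DiGraph()
    g.add_edge(0, a)
    g.add_edge(0, b)
    return PhyloNetwork(g, 0)


def _child_seed(seed: int, name: str) -> int:
    return (seed * 1000003 + zlib.crc32(name.encode())) % (2**31)


def recurse_and_expand(
    net: PhyloNetwork,
    blocks: dict[str, frozenset[str]],
    ts: TripletSet,
    speed: str = "slow",
    seed: int = 0,
    log: list[str] | None = None,
    collector: list[ContractedInstance] | None = None,
) -> PhyloNetwork:
    """Replace each contracted multi-taxon leaf by the network built
    recursively on the block's own restricted triplets."""
    g = net.graph.copy()
    for name in sorted(blocks):
        members = blocks[name]
        if len(members) == 1:
            continue
        if name not in g.nodes:
            raise ValueError(f"contracted leaf {name!r} missing from network")
        if len(members) == 2:
            a, b = sorted(members)
            sub = _cherry_network(a, b)
        else:
            sub_ts = ts.restrict(members)
            sub_net, sub_order, _ = _solve(
                frozenset(members), sub_ts, speed, _child_seed(seed, name), collector
            )
            if log is not None and sub_order:
                log.append(f"block {name}: nested reticulation leaves {sub_order}")
            sub = sub_net
        mapping = {
            v: v if (isinstance(v, str) and sub.graph.out_degree(v) == 0)
            else ("sub", name, i)
            for i, v in enumerate(sub.graph.nodes)
        }
        (p,) = g.predecessors(name)
        g.remove_node(name)
        for u, v in sub.graph.edges:
            g.add_edge(mapping[u], mapping[v])
        g.add_edge(p, mapping[sub.root])
    return PhyloNetwork(g, net.root)


def _solve(
    labels: frozenset[str],
    ts: TripletSet,
    speed: str,
    seed: int,
    collector: list[ContractedInstance] | None = None,
) -> tuple[PhyloNetwork, list[str], list[str]]:
    """One recursion level of the pipeline; returns (network, removal order,
    log lines)."""
    log: list[str] = []
    rng = random.Random(seed)
    g_tau = build_triplet_digraph(ts, labels)
    g_dag = feedback_arc_removal(g_tau)
    n_removed_arcs = g_tau.number_of_edges() - g_dag.number_of_edges()
    if n_removed_arcs:
        log.append(f"feedback-arc removal dropped {n_removed_arcs} arc(s)")
    h = height_from_digraph(g_dag)
    t = hbuild(h, labels)
    if t is not None:
        log.append("HBUILD produced a tree")
        net = PhyloNetwork.from_tree(binarize(t))
        net = patch_inconsistent(net, ts)
        return net, [], log
    weights = {p: h(*p) for p in itertools.combinations(sorted(labels), 2)}
    partition = sn_decompose(labels, weights, ts)
    log.append(
        "SN partition: "
        + ", ".join("{" + ",".join(sorted(b)) + "}" for b in partition)
    )
    inst0 = contract(partition, ts, h)
    if collector is not None:
        collector.append(inst0)
    tau0 = inst0.tau

    def attempt(
        inst: ContractedInstance, removed: list[str]
    ) -> tuple[PhyloNetwork, list[str]]:
        while True:
            tree = build_tree(inst.tau, labels=inst.nodes)
            if tree is not None:
                bt = binarize(tree)
                net = insert_reticulation_leaves(bt, removed, tau0)
                net = recurse_and_expand(
                    net, inst0.blocks, ts, speed, seed, log, collector
                )
                net = patch_inconsistent(net, ts)
                return net, removed
            cands = reticulation_candidates(inst, h, speed, rng)
            if len(cands) == 1:
                removed = removed + [cands[0]]
                inst = inst.remove(cands[0])
                continue
            best = None
            for c in cands:
                res = attempt(inst.remove(c), removed + [c])
                key = (reticulation_count(res[0]), res[1])
                if best is None or key < best[0]:
                    best = (key, res)
            return best[1]

    net, removed = attempt(inst0, [])
    if removed:
        log.append(f"reticulation leaves (removal order): {removed}")
    return net, removed, log


def tripnet(ts: TripletSet, speed: str = "slow", seed: int = 0) -> TripNetResult:
    """Construct a rooted phylogenetic network consistent with every triplet.

    ``speed`` controls how many candidates are branched on when the
    selection criteria tie: ``slow`` examines all of them (smallest result
    wins), ``normal`` two seeded-random picks, ``fast`` one.  Identical
    ``(ts, speed, seed)`` give identical output.
    """
    labels = ts.labels
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    if speed not in ("slow", "normal", "fast"):
        raise ValueError(f"unknown speed mode {speed!r}")
    instances: list[ContractedInstance] = []
    net, removed, log = _solve(frozenset(labels), ts, speed, seed, instances)
    issues = validate_network(net)
    if issues:  # defensive: the construction should always be valid
        raise RuntimeError("constructed network is invalid: " + "; ".join(issues))
    return TripNetResult(net, removed, log, instances)
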