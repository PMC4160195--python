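"""The directed graph ``G_tau`` on taxon pairs and its layered height function.

Every triplet ``ij|k`` orders the pair ``ij`` strictly below the pairs ``ik``
and ``jk`` in any tree realising it, contributing the arcs ``ij -> ik`` and
``ij -> jk``.  Acyclicity of the resulting digraph characterises feasibility
of the integer program IP(tau, s) whose variables are pair heights
``1 <= h(i,j) <= s`` under the constraints ``h(i,j) + 1 <= h(i,k)`` and
``h(i,j) + 1 <= h(j,k)`` per triplet; when ``G_tau`` is a DAG the minimal
feasible ceiling is ``l + 1`` where ``l`` is the longest directed path
length, and the layered (sink-peeling) assignment is the unique pointwise
maximal — hence, under the maximise-sum objective, optimal — solution.

When the input triplets conflict, ``G_tau`` can be cyclic; a deterministic
feedback-arc heuristic removes few arcs to restore acyclicity (any
information lost here is recaptured later by the assembly's patching step).
"""

from __future__ import annotations

import itertools
import random
from typing import Iterable, Mapping

import networkx as nx

from .triplets import TripletSet

__all__ = [
    "Pair",
    "pair",
    "HeightFunction",
    "build_triplet_digraph",
    "is_dag",
    "feedback_arc_removal",
    "height_from_digraph",
    "ip_min_s",
    "verify_optimal_height",
]

#: An unordered taxon pair, stored as a sorted 2-tuple.
Pair = tuple[str, str]


def pair(a: str, b: str) -> Pair:
    """Canonical unordered pair ``{a, b}``."""
    if a == b:
        raise ValueError(f"pair members must be distinct, got {a!r}")
    return (a, b) if a < b else (b, a)


class HeightFunction:
    """A map from taxon pairs to positive integers, bounded by a ceiling ``s``.

    For a tree ``T``, ``h_T(i, j) = l_T - depth(lca(i, j))``; the analogous
    quantity for a triplet set is obtained by layering ``G_tau``.  Heights
    drive both the HBUILD tree construction and the SN-set decomposition.
    """

    def __init__(self, values: Mapping[Pair, int], ceiling: int):
        self.values: dict[Pair, int] = dict(values)
        self.ceiling = int(ceiling)
        for p, v in self.values.items():
            if not 1 <= v <= self.ceiling:
                raise ValueError(f"height {v} of pair {p} outside [1, {ceiling}]")

    def __call__(self, a: str, b: str) -> int:
        return self.values[pair(a, b)]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, HeightFunction)
            and self.values == other.values
            and self.ceiling == other.ceiling
        )

    def __repr__(self) -> str:
        items = ", ".join(f"{a}{b}={v}" for (a, b), v in sorted(self.values.items()))
        return f"HeightFunction({items}; s={self.ceiling})"

    def restrict(self, labels: Iterable[str]) -> "HeightFunction":
        keep = set(labels)
        vals = {p: v for p, v in self.values.items() if p[0] in keep and p[1] in keep}
        return HeightFunction(vals, self.ceiling)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(l for p in self.values for l in p)


def build_triplet_digraph(
    ts: TripletSet, labels: Iterable[str] | None = None
) -> nx.DiGraph:
    """Build ``G_tau`` over ``labels`` (default ``L(tau)``).

    Nodes are all C(n, 2) unordered pairs — pairs mentioned in no triplet stay
    as isolated nodes, which the peeling in :func:`height_from_digraph`
    assigns the maximal height.  Arcs: ``ij -> ik`` and ``ij -> jk`` per
    triplet ``ij|k``, deduplicated.
    """
    lab = sorted(set(labels) if labels is not None else ts.labels)
    if len(lab) < 2:
        raise ValueError("need at least 2 labels to form pairs")
    g = nx.DiGraph()
    g.add_nodes_from(itertools.combinations(lab, 2))
    for t in ts:
        a, b = t.cherry
        c = t.outgroup
        g.add_edge(pair(a, b), pair(a, c))
        g.add_edge(pair(a, b), pair(b, c))
    return g


def is_dag(g: nx.DiGraph) -> bool:
    return nx.is_directed_acyclic_graph(g)


def _find_cycle(g: nx.DiGraph) -> list[Pair] | None:
    """First directed cycle found by DFS from the smallest node, sorted
    neighbour order; None on a DAG."""
    done: set[Pair] = set()
    for start in sorted(g.nodes):
        if start in done:
            continue
        stack: list[tuple[Pair, Iterable[Pair]]] = [(start, iter(sorted(g.successors(start))))]
        on_path = {start}
        order = [start]
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if nxt in on_path:
                    return order[order.index(nxt):]
                if nxt in done:
                    continue
                stack.append((nxt, iter(sorted(g.successors(nxt)))))
                on_path.add(nxt)
                order.append(nxt)
                advanced = True
                break
            if not advanced:
                stack.pop()
                on_path.discard(node)
                order.pop()
                done.add(node)
    return None


def _scc_burden(g: nx.DiGraph) -> int:
    """Number of nodes sitting in nontrivial strongly connected components."""
    return sum(len(c) for c in nx.strongly_connected_components(g) if len(c) > 1)


def feedback_arc_removal(g: nx.DiGraph, seed: int = 0) -> nx.DiGraph:
    """Deterministic feedback-arc heuristic: return an acyclic subgraph.

    While a cycle exists: take the first cycle found by depth-first search
    (smallest start node, sorted neighbours); let ``C_max`` be its nodes of
    maximum total degree in the current graph; among the cycle's arcs incident
    to a ``C_max`` node, remove the one whose removal leaves the fewest nodes
    in nontrivial strongly connected components (greedily losing as little
    ordering information as possible), ties broken lexicographically.
    Idempotent on DAGs; the output arc set is a subset of the input's.

    ``seed`` is accepted for interface symmetry with the randomised
    description of the heuristic; the implementation is fully determinized.
    """
    del seed  # determinized; kept for interface stability
    h = g.copy()
    while True:
        cycle = _find_cycle(h)
        if cycle is None:
            return h
        deg = {v: h.in_degree(v) + h.out_degree(v) for v in cycle}
        dmax = max(deg.values())
        cmax = {v for v, d in deg.items() if d == dmax}
        arcs = []
        for u, v in zip(cycle, cycle[1:] + cycle[:1]):
            if u in cmax or v in cmax:
                arcs.append((u, v))
        best = None
        for arc in sorted(arcs):
            h.remove_edge(*arc)
            score = _scc_burden(h)
            h.add_edge(*arc)
            if best is None or score < best[0]:
                best = (score, arc)
        h.remove_edge(*best[1])


def height_from_digraph(g: nx.DiGraph) -> HeightFunction:
    """Layered height function of a DAG ``G_tau`` (sink-peeling).

    With ``l`` the longest directed path length, repeatedly assign ``l + 1``
    to sinks and peel; equivalently ``h(p) = (l + 1) - (longest path length
    starting at p)``.  Isolated pairs get ``l + 1``; the ceiling is ``l + 1``.
    """
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("height function requires an acyclic pair digraph")
    # longest path length starting at each node, by reverse-topological DP
    lp: dict[Pair, int] = {}
    for node in reversed(list(nx.topological_sort(g))):
        succ = list(g.successors(node))
        lp[node] = 1 + max(lp[s] for s in succ) if succ else 0
    l = max(lp.values(), default=0)
    return HeightFunction({p: l + 1 - v for p, v in lp.items()}, l + 1)


def ip_min_s(ts: TripletSet, labels: Iterable[str] | None = None) -> int | None:
    """Minimal ceiling ``s`` for which IP(tau, s) is feasible, or None.

    Feasibility holds iff ``G_tau`` is acyclic, in which case the minimum is
    the longest path length plus one (the layered heights witness it).
    """
    g = build_triplet_digraph(ts, labels)
    if not nx.is_directed_acyclic_graph(g):
        return None
    return height_from_digraph(g).ceiling


def ip_feasible(ts: TripletSet, h: HeightFunction) -> bool:
    """Check the IP(tau, s) constraints for an explicit assignment."""
    if any(not 1 <= v <= h.ceiling for v in h.values.values()):
        return False
    for t in ts:
        a, b = t.cherry
        c = t.outgroup
        if not (h(a, b) + 1 <= h(a, c) and h(a, b) + 1 <= h(b, c)):
            return False
    return True


def verify_optimal_height(ts: TripletSet, h: HeightFunction) -> bool:
    """True iff ``h`` is the unique maximise-sum optimum of IP(tau, l+1).

    The layered assignment dominates every feasible solution pointwise, so
    optimality is equivalent to equality with :func:`height_from_digraph`
    (which is also checked to be feasible, guarding the implementation).
    """
    g = build_triplet_digraph(ts, h.labels or None)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("IP(tau, s) is infeasible for cyclic pair digraphs")
    opt = height_from_digraph(g)
    return h == opt and ip_feasible(ts, h)
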