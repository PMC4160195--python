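"""Rooted trees from triplets: the Aho/BUILD recursion and HBUILD.

BUILD decides, for a set of rooted triplets, whether some rooted tree is
consistent with all of them, and constructs the (unique, maximally unresolved)
such tree when it exists.  HBUILD answers the same question driven purely by
a height function ``h`` on taxon pairs: it repeatedly deletes the
maximum-weight edge class of the ``h``-weighted complete graph; every
successful split becomes one internal node.  For a triplet set consistent
with a tree, HBUILD applied to the layered heights of ``G_tau`` reproduces
the BUILD tree exactly.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator

import networkx as nx

from .digraph import HeightFunction, Pair, pair
from .triplets import Triplet, TripletSet

__all__ = [
    "RootedTree",
    "aho_graph",
    "build_tree",
    "hbuild",
    "binarize",
    "tree_height_function",
    "tree_consistent_triplet",
    "write_newick",
    "read_newick",
]


class RootedTree:
    """A rooted phylogenetic tree: internal nodes have >= 2 children.

    Leaves are string-labelled graph nodes; internal nodes are integers.
    """

    def __init__(self, graph: nx.DiGraph, root):
        self.graph = graph
        self.root = root
        self._check()

    def _check(self) -> None:
        g = self.graph
        if g.in_degree(self.root) != 0:
            raise ValueError("root must have indegree 0")
        roots = {n for n in g.nodes if g.in_degree(n) == 0}
        if roots != {self.root}:
            raise ValueError("tree must have exactly one root")
        for n in g.nodes:
            out = g.out_degree(n)
            if out == 1:
                raise ValueError(f"internal node {n!r} has a single child")
            if out == 0 and not isinstance(n, str):
                raise ValueError(f"leaf {n!r} is unlabeled")
        if not nx.is_tree(g.to_undirected(as_view=True)):
            raise ValueError("graph is not a tree")

    @property
    def leaves(self) -> frozenset[str]:
        g = self.graph
        return frozenset(n for n in g.nodes if g.out_degree(n) == 0)

    def children(self, node) -> list:
        return list(self.graph.successors(node))

    def is_binary(self) -> bool:
        return all(
            self.graph.out_degree(n) in (0, 2) for n in self.graph.nodes
        )

    def clusters(self) -> frozenset[frozenset[str]]:
        """Leaf sets below each node (the tree's cluster encoding).

        Two trees on the same taxa are isomorphic iff their clusters match.
        """
        below: dict[object, frozenset[str]] = {}
        for n in nx.dfs_postorder_nodes(self.graph, self.root):
            kids = list(self.graph.successors(n))
            below[n] = (
                frozenset([n]) if not kids else frozenset().union(*(below[k] for k in kids))
            )
        return frozenset(below.values())

    def copy(self) -> "RootedTree":
        return RootedTree(self.graph.copy(), self.root)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, RootedTree)
            and self.leaves == other.leaves
            and self.clusters() == other.clusters()
        )

    def __hash__(self) -> int:
        return hash((self.leaves, self.clusters()))

    def __repr__(self) -> str:
        return f"RootedTree({write_newick(self)})"


def _fresh_ids(start: int = 0) -> Iterator[int]:
    return itertools.count(start)


def aho_graph(ts: TripletSet, subset: Iterable[str]) -> nx.Graph:
    """Aho graph on ``subset``: edge {i, j} iff some ``ij|k`` has all three
    labels inside ``subset``.  Its connected components drive BUILD."""
    nodes = set(subset)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for t in ts:
        if t.labels <= nodes:
            g.add_edge(*t.cherry)
    return g


def build_tree(
    ts: TripletSet, labels: Iterable[str] | None = None
) -> RootedTree | None:
    """The BUILD recursion; None when no consistent tree exists.

    ``labels`` defaults to ``L(tau)`` but may be a superset (extra taxa are
    unconstrained and attach at the root of the relevant subproblem).
    """
    lab = set(labels) if labels is not None else set(ts.labels)
    if not lab:
        raise ValueError("cannot build a tree on an empty taxon set")
    ids = _fresh_ids()
    g = nx.DiGraph()

    def rec(nodes: set[str]):
        if len(nodes) == 1:
            (leaf,) = nodes
            g.add_node(leaf)
            return leaf
        comps = list(nx.connected_components(aho_graph(ts, nodes)))
        if len(comps) == 1:
            return None
        me = next(ids)
        for comp in comps:
            sub = rec(comp)
            if sub is None:
                return None
            g.add_edge(me, sub)
        return me

    root = rec(lab)
    return None if root is None else RootedTree(g, root)


def hbuild(h: HeightFunction, labels: Iterable[str]) -> RootedTree | None:
    """Tree realising the height function ``h`` on ``labels``, or None.

    Work on the complete graph weighted by ``h``.  Within each current
    component, delete the whole maximum-weight edge class; if the component
    stays connected no tree realises ``h`` (at any level, not only the
    first).  Otherwise each split event becomes one internal node whose
    children are the sub-components.  When some tree realises ``h``, the
    pairs separated by each split are exactly the maximum-weight class, so
    this recursion reconstructs that tree; the final verification that the
    candidate's height function equals ``h`` therefore makes the decision
    exact (it rejects height functions whose splits merge several weight
    classes at once, which no tree can realise).
    """
    lab = sorted(set(labels))
    if not lab:
        raise ValueError("cannot build a tree on an empty taxon set")
    edges = {p: h(*p) for p in itertools.combinations(lab, 2)}
    ids = _fresh_ids()
    g = nx.DiGraph()

    def components(nodes: set[str], live: dict[Pair, int]) -> list[set[str]]:
        u = nx.Graph()
        u.add_nodes_from(nodes)
        u.add_edges_from(p for p in live if p[0] in nodes and p[1] in nodes)
        return list(nx.connected_components(u))

    def rec(nodes: set[str], live: dict[Pair, int]):
        if len(nodes) == 1:
            (leaf,) = nodes
            g.add_node(leaf)
            return leaf
        inner = {p: w for p, w in live.items() if p[0] in nodes and p[1] in nodes}
        wmax = max(inner.values())
        remaining = {p: w for p, w in inner.items() if w < wmax}
        comps = components(nodes, remaining)
        if len(comps) == 1:
            return None
        me = next(ids)
        for comp in comps:
            sub = rec(comp, remaining)
            if sub is None:
                return None
            g.add_edge(me, sub)
        return me

    root = rec(set(lab), edges)
    if root is None:
        return None
    t = RootedTree(g, root)
    if len(lab) >= 2 and tree_height_function(t).values != dict(edges):
        return None
    return t


def _min_descendant(t: RootedTree) -> dict:
    out: dict[object, str] = {}
    for n in nx.dfs_postorder_nodes(t.graph, t.root):
        kids = list(t.graph.successors(n))
        out[n] = n if not kids else min(out[k] for k in kids)
    return out


def binarize(t: RootedTree, strategy_seed: int = 0) -> RootedTree:
    """Refine every multifurcation to outdegree 2.

    For a node with children ``x1..xk`` (k > 2), ordered by smallest
    descendant label, a fresh node adopts ``x1..x(k-1)``; repeat.  Any
    grouping preserves triplet consistency; this one is fixed for
    determinism (``strategy_seed`` reserved for alternative strategies).
    """
    del strategy_seed
    g = t.graph.copy()
    ids = _fresh_ids(max((n for n in g.nodes if isinstance(n, int)), default=-1) + 1)
    mindesc = _min_descendant(t)
    queue = [n for n in g.nodes if g.out_degree(n) > 2]
    while queue:
        x = queue.pop()
        kids = sorted(g.successors(x), key=lambda c: mindesc[c])
        while len(kids) > 2:
            y = next(ids)
            adopted = kids[:-1]
            for c in adopted:
                g.remove_edge(x, c)
                g.add_edge(y, c)
            g.add_edge(x, y)
            mindesc[y] = min(mindesc[c] for c in adopted)
            x = y
            kids = sorted(g.successors(x), key=lambda c: mindesc[c])
    return RootedTree(g, t.root)


def tree_height_function(t: RootedTree) -> HeightFunction:
    """``h_T(i, j) = l_T - depth(lca(i, j))`` with ``l_T`` the longest
    root-to-node path length."""
    leaves = sorted(t.leaves)
    if len(leaves) < 2:
        raise ValueError("height function needs at least 2 leaves")
    depth = nx.shortest_path_length(t.graph, t.root)
    l_t = max(depth.values())
    anc: dict[str, list] = {}
    for leaf in leaves:
        chain = [leaf]
        while chain[-1] != t.root:
            chain.append(next(iter(t.graph.predecessors(chain[-1]))))
        anc[leaf] = chain
    values = {}
    for a, b in itertools.combinations(leaves, 2):
        common = set(anc[a]) & set(anc[b])
        lca = max(common, key=lambda n: depth[n])
        values[pair(a, b)] = l_t - depth[lca]
    return HeightFunction(values, l_t)


def tree_consistent_triplet(
    t: RootedTree, tr: Triplet, h: HeightFunction | None = None
) -> bool:
    """``ij|k`` is consistent with a tree iff ``h_T(i,j) < h_T(i,k)`` or
    ``h_T(i,j) < h_T(j,k)`` — equivalently lca(i, j) is strictly below
    lca(i, k) or lca(j, k).  Pass a precomputed ``h`` when checking many
    triplets against the same tree."""
    missing = tr.labels - t.leaves
    if missing:
        raise ValueError(f"labels {sorted(missing)} not in the tree")
    if h is None:
        h = tree_height_function(t)
    a, b = tr.cherry
    c = tr.outgroup
    return h(a, b) < h(a, c) or h(a, b) < h(b, c)


def triplets_of_tree(t: RootedTree) -> TripletSet:
    """All triplets consistent with ``t`` (dense when ``t`` is binary)."""
    h = tree_height_function(t)
    out = []
    for a, b, c in itertools.combinations(sorted(t.leaves), 3):
        for tr in (Triplet(a, b, c), Triplet(a, c, b), Triplet(b, c, a)):
            if tree_consistent_triplet(t, tr, h):
                out.append(tr)
    return TripletSet(out)


# ---------------------------------------------------------------------------
# Newick (labels only, no branch lengths; children ordered by smallest
# descendant label for bit-stable output)

def write_newick(t: RootedTree) -> str:
    mindesc = _min_descendant(t)

    def rec(n) -> str:
        kids = sorted(t.graph.successors(n), key=lambda c: mindesc[c])
        if not kids:
            return n
        return "(" + ",".join(rec(k) for k in kids) + ")"

    return rec(t.root) + ";"


def read_newick(text: str) -> RootedTree:
    """Parse label-only Newick into a :class:`RootedTree`."""
    s = text.strip()
    if s.endswith(";"):
        s = s[:-1]
    ids = _fresh_ids()
    g = nx.DiGraph()
    pos = 0

    def parse():
        nonlocal pos
        if pos < len(s) and s[pos] == "(":
            me = next(ids)
            pos += 1  # consume '('
            while True:
                child = parse()
                g.add_edge(me, child)
                if pos >= len(s):
                    raise ValueError("unbalanced parentheses in newick input")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
            # tolerate (and ignore) an internal label
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            return me
        start = pos
        while pos < len(s) and s[pos] not in ",()":
            pos += 1
        label = s[start:pos].strip()
        if not label:
            raise ValueError(f"empty label at position {start} in newick input")
        g.add_node(label)
        return label

    root = parse()
    if pos != len(s):
        raise ValueError(f"trailing characters {s[pos:]!r} in newick input")
    return RootedTree(g, root)
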