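"""Rooted phylogenetic networks: validity, level, heights, triplet consistency.

A rooted phylogenetic network is a rooted DAG whose root has indegree 0 and
outdegree 2 and whose remaining nodes have (in, out) degrees (1, 2) (tree
nodes), (2, 1) (reticulation nodes — hybridization or recombination signal),
or (1, 0) (distinctly labelled leaves).  A triplet ``ij|k`` is consistent
with a network ``N`` when ``N`` contains a subdivision of it: distinct nodes
``u`` and ``v`` with pairwise internally node-disjoint paths ``u -> i``,
``u -> j``, ``v -> u`` and ``v -> k``.

The network height ``h_N(i, j)`` generalises the tree height via
longest-path depths and the (non-unique) lowest common ancestors; a strict
inequality ``h_N(i,j) < h_N(i,k)`` or ``h_N(i,j) < h_N(j,k)`` is sufficient
(not necessary) for consistency of ``ij|k``, which gives the consistency
decision below its fast path; the exact decision enumerates subdivision
witnesses.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Iterator

import networkx as nx

from .digraph import HeightFunction, pair
from .trees import RootedTree
from .triplets import Triplet, TripletSet

__all__ = [
    "PhyloNetwork",
    "NetworkHeight",
    "validate_network",
    "reticulation_count",
    "network_level",
    "network_height_function",
    "triplet_consistent",
    "consistent_triplet_set",
    "network_from_height",
    "to_enewick",
    "from_enewick",
    "write_edge_list",
    "read_edge_list",
    "isomorphic",
]


class PhyloNetwork:
    """A rooted DAG with string-labelled leaves (outdegree-0 nodes).

    Instances are treated as immutable once constructed (derived data such as
    reachability and heights is cached); builders create fresh objects.
    """

    def __init__(self, graph: nx.DiGraph, root=None):
        self.graph = graph
        if root is None:
            roots = [n for n in graph.nodes if graph.in_degree(n) == 0]
            if len(roots) != 1:
                raise ValueError(f"expected exactly one root, found {len(roots)}")
            root = roots[0]
        self.root = root

    @classmethod
    def from_tree(cls, t: RootedTree) -> "PhyloNetwork":
        return cls(t.graph.copy(), t.root)

    def to_tree(self) -> RootedTree:
        if self.reticulations:
            raise ValueError("network has reticulation nodes; not a tree")
        return RootedTree(self.graph.copy(), self.root)

    @property
    def leaves(self) -> frozenset[str]:
        g = self.graph
        return frozenset(n for n in g.nodes if g.out_degree(n) == 0)

    @cached_property
    def reticulations(self) -> frozenset:
        g = self.graph
        return frozenset(n for n in g.nodes if g.in_degree(n) == 2)

    @cached_property
    def descendants(self) -> dict:
        """node -> set of nodes reachable from it (including itself)."""
        out: dict = {}
        for n in reversed(list(nx.topological_sort(self.graph))):
            s = {n}
            for c in self.graph.successors(n):
                s |= out[c]
            out[n] = s
        return out

    @cached_property
    def height(self) -> "NetworkHeight":
        return network_height_function(self)

    def copy_graph(self) -> nx.DiGraph:
        return self.graph.copy()

    def __repr__(self) -> str:
        return f"PhyloNetwork({to_enewick(self)})"


def validate_network(n: PhyloNetwork) -> list[str]:
    """All violations of the rooted-network degree/reachability rules.

    Empty list iff ``n`` is a valid rooted phylogenetic network.  Violations
    are returned as data rather than raised so callers can report them all.
    """
    g = n.graph
    issues: list[str] = []
    if not nx.is_directed_acyclic_graph(g):
        issues.append("graph contains a directed cycle")
        return issues
    roots = [v for v in g.nodes if g.in_degree(v) == 0]
    if len(roots) != 1:
        issues.append(f"expected 1 indegree-0 node, found {len(roots)}")
    else:
        r = roots[0]
        if g.out_degree(r) != 2:
            issues.append(f"root has outdegree {g.out_degree(r)}, expected 2")
        unreachable = set(g.nodes) - set(nx.descendants(g, r)) - {r}
        if unreachable:
            issues.append(f"{len(unreachable)} node(s) unreachable from the root")
    for v in g.nodes:
        if v in roots:
            continue
        deg = (g.in_degree(v), g.out_degree(v))
        if deg not in ((2, 1), (1, 2), (1, 0)):
            issues.append(f"node {v!r} has (in, out) degrees {deg}")
        if deg == (1, 0) and not isinstance(v, str):
            issues.append(f"leaf {v!r} is unlabeled")
    return issues


def reticulation_count(n: PhyloNetwork) -> int:
    return len(n.reticulations)


def network_level(n: PhyloNetwork) -> int:
    """Maximum number of reticulation nodes in any biconnected component.

    A reticulation is charged to the biconnected component (of the
    underlying undirected graph) containing its two parent edges — they
    always share one, since the two parents have a common ancestor.
    A tree is a level-0 network.
    """
    issues = validate_network(n)
    if issues:
        raise ValueError("invalid network: " + "; ".join(issues))
    und = nx.Graph(n.graph.to_undirected(as_view=False))
    best = 0
    for comp_edges in nx.biconnected_component_edges(und):
        eset = {frozenset(e) for e in comp_edges}
        count = sum(
            1
            for r in n.reticulations
            if all(frozenset((p, r)) in eset for p in n.graph.predecessors(r))
        )
        best = max(best, count)
    return best


@dataclass
class NetworkHeight:
    """Longest-path depths and the induced height function of a network."""

    l_n: int
    depth: dict
    h: HeightFunction


def network_height_function(n: PhyloNetwork) -> NetworkHeight:
    """``h_N(i, j) = min{ l_N - d(r, c) : c a lowest common ancestor }``.

    ``d(r, u)`` is the LONGEST directed path length from the root (computed
    by DAG dynamic programming), ``l_N`` the longest root-to-leaf length, and
    a lowest common ancestor is a common ancestor from which no other common
    ancestor is reachable.
    """
    g = n.graph
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("network must be acyclic")
    depth: dict = {}
    for v in nx.topological_sort(g):
        preds = list(g.predecessors(v))
        depth[v] = 0 if not preds else 1 + max(depth[p] for p in preds)
    leaves = sorted(n.leaves)
    l_n = max(depth[x] for x in leaves)
    desc = n.descendants
    values = {}
    for a, b in itertools.combinations(leaves, 2):
        common = [c for c in g.nodes if a in desc[c] and b in desc[c]]
        lowest = [
            c for c in common
            if not any(c2 != c and c2 in desc[c] for c2 in common)
        ]
        values[pair(a, b)] = min(l_n - depth[c] for c in lowest)
    return NetworkHeight(l_n, depth, HeightFunction(values, l_n))


# ---------------------------------------------------------------------------
# exact triplet consistency

def _paths(g: nx.DiGraph, src, dst, banned: set) -> Iterator[tuple]:
    """All simple directed paths src -> dst whose nodes avoid ``banned``
    (endpoints exempt).  DAG recursion; yields node tuples."""
    if src == dst:
        yield (src,)
        return
    for nxt in sorted(g.successors(src), key=str):
        if nxt != dst and nxt in banned:
            continue
        for rest in _paths(g, nxt, dst, banned):
            yield (src,) + rest


def _reaches_avoiding(g: nx.DiGraph, src, dst, banned: set) -> bool:
    """Is there a directed path src -> dst with intermediates outside
    ``banned``?  (src/dst themselves exempt.)"""
    stack = [src]
    seen = {src}
    while stack:
        v = stack.pop()
        for w in g.successors(v):
            if w == dst:
                return True
            if w in banned or w in seen:
                continue
            seen.add(w)
            stack.append(w)
    return False


def triplet_consistent(n: PhyloNetwork, tr: Triplet) -> bool:
    """Exact decision whether ``n`` contains a subdivision of ``tr``.

    Fast paths: on a tree the height criterion is exact; on a network a
    strict height inequality is a proven sufficient condition.  Otherwise
    subdivision witnesses (u, v) are enumerated: all internally-disjoint
    path pairs u -> i, u -> j, then paths v -> u avoiding them, then a
    reachability check v -> k avoiding everything used.
    """
    missing = tr.labels - n.leaves
    if missing:
        raise ValueError(f"labels {sorted(missing)} not in the network")
    a, b = tr.cherry
    k = tr.outgroup
    h = n.height.h
    if h(a, b) < h(a, k) or h(a, b) < h(b, k):
        return True  # sufficient in any network
    if not n.reticulations:
        return False  # necessary and sufficient in a tree
    g = n.graph
    desc = n.descendants
    for u in sorted(g.nodes, key=str):
        if u in (a, b, k) or a not in desc[u] or b not in desc[u]:
            continue
        for p1 in _paths(g, u, a, {b, k}):
            block1 = set(p1) - {u}
            for p2 in _paths(g, u, b, block1 | {k}):
                blocked = block1 | set(p2) - {u}
                for v in sorted(g.nodes, key=str):
                    if v == u or v in blocked:
                        continue
                    if u not in desc[v] or k not in desc[v]:
                        continue
                    for p3 in _paths(g, v, u, blocked | {a, b, k}):
                        used = blocked | set(p3) - {v}
                        if _reaches_avoiding(g, v, k, used | {u}):
                            return True
    return False


def consistent_triplet_set(n: PhyloNetwork) -> TripletSet:
    """``tau(N)``: every triplet over 3-subsets of the leaves consistent
    with ``n``.  Dense by construction for binary trees."""
    leaves = sorted(n.leaves)
    if len(leaves) < 3:
        raise ValueError("need at least 3 leaves")
    out = []
    for x, y, z in itertools.combinations(leaves, 3):
        for tr in (Triplet(x, y, z), Triplet(x, z, y), Triplet(y, z, x)):
            if triplet_consistent(n, tr):
                out.append(tr)
    return TripletSet(out)


# ---------------------------------------------------------------------------
# realising a height function (meeting-node construction + normalization)

def network_from_height(
    h: HeightFunction, labels: Iterable[str], normalize: bool = True
) -> PhyloNetwork:
    """Build a valid network realising ``h`` (up to the +1 depth shift).

    Raw construction: for each pair at the maximal height, two root paths of
    length ``h_max`` to the pair's attachment nodes; for lower pairs, a
    meeting node hung ``h_max - h`` below the root, joined to both
    attachment nodes; each attachment node feeds its leaf.  The raw object
    satisfies ``h_N = h + 1`` but violates the degree rules, so it is then
    normalized: unary paths suppressed, indegree-``d`` attachment nodes
    replaced by a reticulation chain of length ``d - 2``, and fan-outs
    (notably the root's) binarized.  Consistency is only gained, never lost,
    by the normalization.  ``normalize=False`` returns the raw construction
    (useful for checking its exact height property; it is not a valid
    network).
    """
    lab = sorted(set(labels))
    if len(lab) < 2:
        raise ValueError("need at least 2 labels")
    ids = itertools.count()
    g = nx.DiGraph()
    root = ("root", next(ids))
    g.add_node(root)
    attach = {x: ("attach", x) for x in lab}
    for x in lab:
        g.add_edge(attach[x], x)
    hmax = max(h(a, b) for a, b in itertools.combinations(lab, 2))

    def chain(frm, to, length: int) -> None:
        cur = frm
        for _ in range(length - 1):
            nxt = ("path", next(ids))
            g.add_edge(cur, nxt)
            cur = nxt
        g.add_edge(cur, to)

    for a, b in itertools.combinations(lab, 2):
        if h(a, b) == hmax:
            chain(root, attach[a], hmax)
            chain(root, attach[b], hmax)
        else:
            m = ("meet", next(ids))
            chain(root, m, hmax - h(a, b))
            g.add_edge(m, attach[a])
            g.add_edge(m, attach[b])
    if not normalize:
        return PhyloNetwork(g, root)
    return _normalize(g, root, ids)


def _normalize(g: nx.DiGraph, root, ids) -> PhyloNetwork:
    # 1. suppress unary (indeg<=1, outdeg==1) inner nodes
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if v == root and g.out_degree(v) == 1:
                # unary root: its single child becomes the root
                (c,) = g.successors(v)
                g.remove_node(v)
                root = c
                changed = True
            elif g.in_degree(v) == 1 and g.out_degree(v) == 1:
                (p,) = g.predecessors(v)
                (c,) = g.successors(v)
                g.remove_node(v)
                if p != c:
                    g.add_edge(p, c)  # parallel routes collapse
                changed = True
    # 2. fan-in: replace indegree-d (>2) nodes by a reticulation chain
    for v in [v for v in list(g.nodes) if g.in_degree(v) > 2]:
        parents = sorted(g.predecessors(v), key=str)
        d = len(parents)
        (child,) = g.successors(v)
        g.remove_edge(v, child)
        cur = v
        for i in range(d - 2):
            w = ("ret", next(ids))
            g.add_edge(cur, w)
            g.remove_edge(parents[i], v)
            g.add_edge(parents[i], w)
            cur = w
        g.add_edge(cur, child)
    # 3. binarize fan-outs (the root in particular)
    for v in [v for v in list(g.nodes) if g.out_degree(v) > 2]:
        kids = sorted(g.successors(v), key=str)
        while len(kids) > 2:
            y = ("bin", next(ids))
            for c in kids[:-1]:
                g.remove_edge(v, c)
                g.add_edge(y, c)
            g.add_edge(v, y)
            v = y
            kids = sorted(g.successors(v), key=str)
    # a fan-in pass can leave fresh unary nodes behind; one more sweep
    for v in list(g.nodes):
        if v != root and g.in_degree(v) == 1 and g.out_degree(v) == 1:
            (p,) = g.predecessors(v)
            (c,) = g.successors(v)
            g.remove_node(v)
            if p != c:
                g.add_edge(p, c)
    return PhyloNetwork(g, root)


# ---------------------------------------------------------------------------
# eNewick serialisation ('#H<k>' hybrid tags, no branch lengths, children in
# lexicographic order of smallest descendant label)

def _min_desc_label(n: PhyloNetwork) -> dict:
    out: dict = {}
    for v in reversed(list(nx.topological_sort(n.graph))):
        kids = list(n.graph.successors(v))
        out[v] = v if not kids else min(out[c] for c in kids)
    return out


def to_enewick(n: PhyloNetwork) -> str:
    """Serialise; trees come out as plain Newick, each reticulation node
    appears once in full ('(...)#Hk') and as a '#Hk' stub elsewhere."""
    mind = _min_desc_label(n)
    rets = sorted(n.reticulations, key=lambda v: (mind[v], str(v)))
    tag = {v: f"#H{i}" for i, v in enumerate(rets, start=1)}
    # primary parent: first in sorted order
    primary = {
        v: min(n.graph.predecessors(v), key=lambda p: (mind[p], str(p)))
        for v in rets
    }

    def rec(v, parent) -> str:
        if v in tag:
            if parent != primary[v]:
                return tag[v]
            (child,) = n.graph.successors(v)
            return "(" + rec(child, v) + ")" + tag[v]
        kids = sorted(n.graph.successors(v), key=lambda c: (mind[c], str(c)))
        if not kids:
            return v
        return "(" + ",".join(rec(c, v) for c in kids) + ")"

    return rec(n.root, None) + ";"


_LABEL_RE = re.compile(r"[^(),;#]*")


def from_enewick(text: str) -> PhyloNetwork:
    """Parse the eNewick dialect written by :func:`to_enewick`."""
    s = text.strip()
    if s.endswith(";"):
        s = s[:-1]
    ids = itertools.count()
    g = nx.DiGraph()
    hybrids: dict[str, object] = {}
    pos = 0

    def hybrid_node(tagname: str):
        if tagname not in hybrids:
            hybrids[tagname] = ("hybrid", tagname)
            g.add_node(hybrids[tagname])
        return hybrids[tagname]

    def parse():
        nonlocal pos
        children = []
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                children.append(parse())
                if pos >= len(s):
                    raise ValueError("unbalanced parentheses in eNewick input")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        m = _LABEL_RE.match(s, pos)
        label = m.group(0)
        pos = m.end()
        tagname = None
        if pos < len(s) and s[pos] == "#":
            m2 = re.match(r"#H?\d+", s[pos:])
            if not m2:
                raise ValueError(f"malformed hybrid tag at position {pos}")
            tagname = m2.group(0)
            pos += len(tagname)
        if tagname is not None:
            node = hybrid_node(tagname)
        elif children:
            node = ("inner", next(ids))
            g.add_node(node)
        else:
            if not label:
                raise ValueError(f"empty leaf label near position {pos}")
            node = label
            g.add_node(node)
        for c in children:
            g.add_edge(node, c)
        return node

    root = parse()
    if pos != len(s):
        raise ValueError(f"trailing characters {s[pos:]!r} in eNewick input")
    return PhyloNetwork(g, root)


def write_edge_list(n: PhyloNetwork) -> str:
    """Unambiguous debug format: one ``parent<TAB>child`` line per arc."""
    names = _node_names(n)
    lines = sorted(f"{names[u]}\t{names[v]}" for u, v in n.graph.edges)
    return "\n".join(lines) + "\n"


def _node_names(n: PhyloNetwork) -> dict:
    names = {}
    taken = set(n.leaves)
    counter = itertools.count(1)
    for v in nx.topological_sort(n.graph):
        if isinstance(v, str) and n.graph.out_degree(v) == 0:
            names[v] = v
        else:
            name = f"_{next(counter)}"
            while name in taken:
                name = f"_{next(counter)}"
            names[v] = name
        taken.add(names[v])
    return names


def read_edge_list(text: str) -> PhyloNetwork:
    g = nx.DiGraph()
    for num, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"line {num}: expected 'parent<TAB>child'")
        g.add_edge(parts[0], parts[1])
    return PhyloNetwork(g)


def isomorphic(n1: PhyloNetwork, n2: PhyloNetwork) -> bool:
    """Digraph isomorphism respecting leaf labels."""
    def tag(g):
        h = g.copy()
        for v in h.nodes:
            h.nodes[v]["label"] = v if h.out_degree(v) == 0 else None
        return h

    return nx.is_isomorphic(
        tag(n1.graph), tag(n2.graph),
        node_match=lambda x, y: x["label"] == y["label"],
    )
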