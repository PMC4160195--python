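"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's shortcuts: triplet consistency
is decided by exhaustively enumerating subdivision witnesses with explicit
pairwise-disjointness checks, and the minimal feasible height-program
ceiling is found by generic interval propagation plus backtracking over raw
integer assignments, never by longest-path layering.
"""

from __future__ import annotations

import itertools

import networkx as nx

from tripnet import PhyloNetwork, Triplet, TripletSet


def consistency_oracle(net: PhyloNetwork, tr: Triplet) -> bool:
    """Exhaustive search for a subdivision of the triplet in the network:
    nodes u, v with pairwise internally node-disjoint paths u->i, u->j,
    v->u, v->k."""
    g = net.graph
    a, b = tr.cherry
    k = tr.outgroup

    def paths(s, t):
        if s == t:
            return [(s,)]
        return [tuple(p) for p in nx.all_simple_paths(g, s, t)]

    for u in g.nodes:
        for v in g.nodes:
            if u == v:
                continue
            for p1 in paths(u, a):
                s1 = set(p1)
                for p2 in paths(u, b):
                    s2 = set(p2)
                    if s1 & s2 != {u}:
                        continue
                    for p3 in paths(v, u):
                        s3 = set(p3)
                        if s1 & s3 != {u} or s2 & s3 != {u}:
                            continue
                        for p4 in paths(v, k):
                            s4 = set(p4)
                            if s3 & s4 == {v} and not s1 & s4 and not s2 & s4:
                                return True
    return False


def _csp_feasible(cons: list[tuple[int, int]], n_vars: int, s: int) -> bool:
    """Backtracking search with interval bounds over the raw constraints
    ``h[lo] + 1 <= h[up]``, ``1 <= h <= s``."""
    lb = [1] * n_vars
    ub = [s] * n_vars

    def propagate() -> bool:
        changed = True
        while changed:
            changed = False
            for lo, up in cons:
                if lb[lo] + 1 > lb[up]:
                    lb[up] = lb[lo] + 1
                    changed = True
                if ub[up] - 1 < ub[lo]:
                    ub[lo] = ub[up] - 1
                    changed = True
            if any(lb[i] > ub[i] for i in range(n_vars)):
                return False
        return True

    def bt(i: int) -> bool:
        nonlocal lb, ub
        if not propagate():
            return False
        if i == n_vars:
            return True
        saved = (lb[:], ub[:])
        for v in range(lb[i], ub[i] + 1):
            lb[i] = ub[i] = v
            if bt(i + 1):
                return True
            lb, ub = saved[0][:], saved[1][:]
        return False

    return bt(0)


def ip_min_s_oracle(ts: TripletSet, labels, s_cap: int | None = None) -> int | None:
    """Smallest feasible ceiling of the pair-height integer program, by
    explicit search; None when no ceiling up to ``s_cap`` works."""
    lab = sorted(labels)
    pairs = [tuple(sorted(p)) for p in itertools.combinations(lab, 2)]
    idx = {p: n for n, p in enumerate(pairs)}
    if s_cap is None:
        s_cap = len(pairs)
    cons = []
    for t in ts:
        a, b = t.cherry
        c = t.outgroup
        lo = idx[tuple(sorted((a, b)))]
        for up in ((a, c), (b, c)):
            cons.append((lo, idx[tuple(sorted(up))]))
    for s in range(1, s_cap + 1):
        if _csp_feasible(cons, len(pairs), s):
            return s
    return None


def ip_min_s_exhaustive(ts: TripletSet, labels, s_cap: int) -> int | None:
    """Tiny-instance variant: literally try every integer assignment."""
    lab = sorted(labels)
    pairs = [tuple(sorted(p)) for p in itertools.combinations(lab, 2)]
    idx = {p: n for n, p in enumerate(pairs)}
    cons = []
    for t in ts:
        a, b = t.cherry
        c = t.outgroup
        lo = idx[tuple(sorted((a, b)))]
        for up in ((a, c), (b, c)):
            cons.append((lo, idx[tuple(sorted(up))]))
    for s in range(1, s_cap + 1):
        for assign in itertools.product(range(1, s + 1), repeat=len(pairs)):
            if all(assign[lo] + 1 <= assign[up] for lo, up in cons):
                return s
    return None
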