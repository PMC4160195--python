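"""Synthetic trees, networks, triplet samples and distance matrices.

These generators stand in for sequence-simulation pipelines at desk scale:
random Yule trees and low-level networks provide ground truth, their
consistent triplet sets (optionally subsampled to non-dense sets) provide
inputs, and ultrametric-plus-noise matrices feed the distance-based triplet
rule the same way an external distance estimate would.
"""

from __future__ import annotations

import itertools
import random

import networkx as nx
import numpy as np

from .network import PhyloNetwork, consistent_triplet_set, validate_network
from .trees import RootedTree, triplets_of_tree, tree_height_function
from .triplets import DistanceMatrix, TripletSet

__all__ = [
    "random_binary_tree",
    "random_network",
    "triplets_from",
    "distance_matrix_from_tree",
]


def _default_labels(n: int) -> list[str]:
    return [f"t{i}" for i in range(1, n + 1)]


def random_binary_tree(
    n: int, seed: int = 0, labels: list[str] | None = None
) -> RootedTree:
    """Yule (uniform leaf-attachment) random binary tree on ``n`` leaves."""
    if n < 2:
        raise ValueError("need at least 2 leaves")
    labels = list(labels) if labels is not None else _default_labels(n)
    if len(labels) != n:
        raise ValueError("label count must equal n")
    rng = random.Random(seed)
    order = labels[:]
    rng.shuffle(order)
    g = nx.DiGraph()
    ids = itertools.count()
    root = next(ids)
    g.add_edge(root, order[0])
    g.add_edge(root, order[1])
    for new_leaf in order[2:]:
        leaf = rng.choice(sorted(v for v in g.nodes if g.out_degree(v) == 0))
        (p,) = g.predecessors(leaf)
        mid = next(ids)
        g.remove_edge(p, leaf)
        g.add_edge(p, mid)
        g.add_edge(mid, leaf)
        g.add_edge(mid, new_leaf)
    return RootedTree(g, root)


def random_network(
    n: int, r: int, seed: int = 0, labels: list[str] | None = None
) -> PhyloNetwork:
    """Random network: a Yule tree plus ``r`` reticulation events.

    Each event subdivides two distinct edges and joins the new nodes by an
    arc; placements that would create a cycle are rejected and resampled
    (bounded retries).  The result is always a valid network with exactly
    ``r`` reticulation nodes.
    """
    if r < 0:
        raise ValueError("reticulation count must be non-negative")
    t = random_binary_tree(n, seed, labels)
    g = t.graph.copy()
    rng = random.Random(seed + 1)
    ids = itertools.count(max(v for v in g.nodes if isinstance(v, int)) + 1)
    for _ in range(r):
        for _retry in range(200):
            edges = sorted(g.edges, key=str)
            e1, e2 = rng.sample(edges, 2)
            # cycle arises iff the head side of e2 can already reach e1
            if nx.has_path(g, e2[1], e1[0]) or e2[1] == e1[0]:
                continue
            u1, u2 = next(ids), next(ids)
            for (a, b), u in ((e1, u1), (e2, u2)):
                g.remove_edge(a, b)
                g.add_edge(a, u)
                g.add_edge(u, b)
            g.add_edge(u1, u2)
            break
        else:
            raise RuntimeError("could not place a reticulation acyclically")
    net = PhyloNetwork(g, t.root)
    issues = validate_network(net)
    if issues:
        raise RuntimeError("generator produced an invalid network: " + "; ".join(issues))
    return net


def triplets_from(
    source: RootedTree | PhyloNetwork, fraction: float = 1.0, seed: int = 0
) -> TripletSet:
    """Consistent triplets of a tree or network, subsampled per 3-subset.

    Each 3-subset of the leaves keeps all of its consistent triplets with
    probability ``fraction`` and drops them otherwise, so ``fraction < 1``
    yields non-dense inputs while every emitted triplet stays consistent
    with the source.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if isinstance(source, RootedTree):
        full = triplets_of_tree(source)
    else:
        full = consistent_triplet_set(source)
    if fraction == 1:
        return full
    rng = random.Random(seed)
    keep_subset = {
        s: rng.random() < fraction
        for s in sorted(
            {frozenset(t.labels) for t in full}, key=sorted
        )
    }
    return TripletSet(t for t in full if keep_subset[frozenset(t.labels)])


def distance_matrix_from_tree(
    t: RootedTree, noise_sd: float = 0.0, seed: int = 0
) -> DistanceMatrix:
    """Ultrametric distances ``d(i, j) = 2 * h_T(i, j)`` plus optional
    symmetric Gaussian noise, floored at a small positive value."""
    if not t.is_binary():
        raise ValueError("expected a binary tree")
    labels = sorted(t.leaves)
    h = tree_height_function(t)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = 2.0 * h(labels[i], labels[j])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=(n, n))
        noise = (noise + noise.T) / 2.0
        np.fill_diagonal(noise, 0.0)
        d = np.maximum(d + noise, 0.01)
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d)
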