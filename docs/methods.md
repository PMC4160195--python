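# Methods

## Scope and objects

The package builds a rooted phylogenetic network consistent with every
member of an arbitrary finite set τ of rooted triplets on taxa
`L(τ)`.  A valid network here is a rooted DAG whose root has degrees
(in, out) = (0, 2) and whose other nodes are tree nodes (1, 2),
reticulation nodes (2, 1), or labelled leaves (1, 0).  The *level* of a
network is the maximum number of reticulation nodes in a biconnected
component of its underlying undirected graph; a reticulation is charged to
the component containing both of its parent edges.  Consistency of `ij|k`
with a network is the subdivision condition (nodes u, v with pairwise
internally node-disjoint paths u→i, u→j, v→u, v→k) and is decided exactly
(see below), never approximated.

Reticulation minimisation is heuristic: the output is always consistent
with all of τ, and the reticulation count is kept small by the selection
criteria and (in `slow` mode) exhaustive branching, but no global
optimality is claimed — the underlying decision problems are NP-hard.

## Height functions

For a tree, `h_T(i,j) = l_T − depth(lca(i,j))` (longest root path `l_T`,
depths in edges).  For a network, depths are **longest**-path depths
computed by DAG dynamic programming, lowest common ancestors are the
minimal elements (under reachability) of the common-ancestor set, and
`h_N(i,j)` minimises `l_N − d(r,c)` over them.  A strict inequality
`h_N(i,j) < h_N(i,k)` or `h_N(i,j) < h_N(j,k)` is sufficient for
consistency of `ij|k` in any network and also necessary in a tree; in
general networks the converse fails, and the test suite carries a frozen
witness network found by seeded search (a consistent triplet with no strict
inequality).

For a triplet set, heights come from the pair digraph `G_τ` (arcs
`ij → ik`, `ij → jk` per triplet).  Sink-peeling assigns `h(p) = l + 1 −
(longest path from p)` with ceiling `s = l + 1`.  This assignment is
feasible for the integer program {`h(i,j)+1 ≤ h(i,k)`, `h(i,j)+1 ≤ h(j,k)`,
`1 ≤ h ≤ s`} exactly when `G_τ` is acyclic, `s = l + 1` is the minimal
feasible ceiling, and the layered assignment dominates every feasible
solution pointwise — so under the maximise-sum objective it is the unique
optimum.  The objective direction is a design choice: maximisation is the
direction under which the layered solution is the unique optimum, and the
package solves the program combinatorially rather than through an LP/IP
solver (the test suite cross-checks against a generic interval-propagation
search over raw integer assignments).

Pairs that appear in no triplet are kept as isolated digraph nodes and
receive the maximal height, which the peeling forces.

## Exactness of HBUILD

HBUILD deletes, within each current component of the height-weighted
complete graph, the entire maximum-weight edge class; a component that
stays connected means failure (at any recursion level), otherwise each
split becomes an internal node.  Deletion alone is not a sufficient test:
a split can silently merge several weight classes (a deleted maximum-weight
edge whose endpoints remain connected through lighter edges), and the
resulting tree then fails to realise `h` although every removal
disconnected something.  The implementation therefore verifies that the
candidate tree's height function equals `h` and fails otherwise.  This is
exact in both directions: when some tree realises `h`, the pairs separated
at each split are precisely the maximum-weight class, so the recursion
reconstructs that tree and the verification passes.

A consequence worth documenting: for *sparse* tree-compatible triplet sets
the layered heights of `G_τ` can sit strictly above every realisable height
function (e.g. τ = {ab|e, ac|f, bc|e, bd|e, bf|c, bf|d}), so HBUILD
correctly fails there even though BUILD succeeds.  For the dense triplet
set of a binary tree the layered heights equal the tree's own height
function and HBUILD returns exactly the BUILD tree (tested).  The pipeline
is indifferent: a failed HBUILD falls through to the SN decomposition,
which recovers tree-compatible inputs with zero reticulations.

## The pipeline

1. **Feedback arcs.**  If `G_τ` is cyclic the heuristic repeatedly takes
   the first cycle found by depth-first search (smallest start node, sorted
   neighbours), restricts attention to the cycle's arcs incident to a
   maximum-total-degree node, and removes the arc whose removal leaves the
   fewest nodes in nontrivial strongly connected components (ties
   lexicographic).  The greedy look-ahead implements "lose as little
   ordering information as possible"; removed information is recaptured by
   the final patching step.  The procedure is fully determinized — the
   `seed` parameter is accepted for interface stability but unused.
2. **HBUILD** on the layered heights; success returns a binarization
   (multifurcations resolved by grouping the first k−1 children in order of
   smallest descendant label — any grouping preserves triplet consistency;
   this one is fixed for determinism).
3. **SN decomposition.**  A subset S is an SN-set when no triplet `ij|k`
   has one cherry member outside S with the other cherry member and the
   outgroup inside.  Components produced by repeated maximum-weight-class
   deletion become blocks when they are SN-sets and are decomposed further
   otherwise.  Blocks are contracted to single nodes; contracted triplets
   keep only label triples spanning three distinct blocks; contracted edge
   weights are minima of leaf-level heights.  Re-running the decomposition
   on a contracted instance yields only singletons (asserted in tests on
   every instance the pipeline creates).
4. **Reticulation-leaf selection.**  While the contracted triplets admit no
   tree (decided exactly by BUILD on the contracted instance), candidates
   are ranked by three short-circuiting criteria: (I) smallest minimum —
   then smallest maximum — *leaf-level* height of edges leaving the block,
   computed on the surviving taxa; (II) largest degree in the subgraph of
   globally minimum-weight contracted edges; (III) deleting the candidate
   together with its triplets and re-decomposing should produce the most
   SN-sets containing more than one *contracted* node.  Criterion III's
   cardinality is counted in nodes of the contracted graph (the graph being
   decomposed), not in underlying leaves — with leaf-level counting the
   worked 15-triplet example ties and the cascade loses its discriminating
   power.  If several candidates survive, the speed mode decides: `slow`
   branches on all of them and keeps the branch whose *completed* run
   (through patching and recursion) has the fewest reticulations (ties by
   lexicographic removal order); `normal` branches on two seeded-random
   candidates; `fast` takes one.  Only `fast` has a polynomial worst case;
   `slow` is the default because desk-scale instances are small and
   exhaustive branching matches the intent of examining every candidate.
5. **Re-insertion.**  Removed leaves return in reverse order.  For each,
   every unordered pair of distinct current edges is subdivided, the two
   new nodes feed a fresh reticulation node above the leaf, and the pair
   keeping the most contracted triplets (restricted to the labels present)
   consistent wins; ties go to the first pair in a deterministic DFS-based
   edge order.  The objective counts *contracted* triplets because only
   contracted taxa exist at this stage; full-input accounting is deferred
   to the patching step.
6. **Expansion.**  Each multi-taxon block is solved recursively on τ
   restricted to the block (the recursion carries the full block label set,
   so labels absent from every restricted triplet are still placed); the
   block's network root replaces the contracted leaf in place.  Recursion
   depth equals the SN-nesting depth and the taxon count strictly
   decreases, so no explicit cap is needed.
7. **Patching.**  Triplets still inconsistent with the assembled network
   are grouped by cherry; the most-offended pair `{i,j}` gets a new arc
   between subdivisions of its two pendant edges (tail on the
   lexicographically smaller leaf's edge, reversed if that orientation
   leaves part of the group inconsistent).  Both subdivision nodes sit on
   pendant edges, so acyclicity is automatic and no parallel edges can
   arise.  Each round settles its group, the inconsistent set strictly
   shrinks, and termination is guaranteed; the final network is consistent
   with every input triplet.

After one contraction round the pipeline does not contract again: the tree
on the surviving contracted nodes is built directly by BUILD once the
instance becomes tree-compatible, which matches how the worked examples
resolve and avoids HBUILD-on-contracted-weights failures for
tree-compatible contracted sets (the contracted minimum-weights are
generally not a realisable height function even when a tree exists).

## Exact consistency decision

`triplet_consistent` short-circuits through the height inequality
(sufficient always, exact on trees) and otherwise enumerates subdivision
witnesses: candidate nodes u reaching both cherry leaves, all
internally-disjoint path pairs from u, then candidate v and paths v→u
avoiding them, finishing with a reachability check v→k.  On the
low-reticulation networks this package targets, path counts are small; the
test suite verifies exact agreement with an independent brute-force
enumeration on hundreds of random networks.

## Distance-based triplet inference

Given a labelled symmetric matrix, `ij|k` is emitted for a 3-subset exactly
when `D_ij < min(D_ik, D_jk)`; ties yield nothing, so outputs are generally
non-dense.  In dense mode ties are broken by a seeded uniform choice among
the triplets whose cherry attains the minimum (two candidates on a two-way
tie, three on a three-way tie).  Tie detection is exact on the stored
values — no epsilon — because the rule is defined on the given matrix, not
on a noise model; callers may pre-round.

## Synthetic data

The generators emulate the study conditions at desk scale: Yule
(uniform-leaf-attachment) random binary trees; random networks obtained by
adding r reticulation events (two random edges subdivided and connected,
rejecting acyclicity violations); triplet inputs as the full consistent set
(dense for binary trees) or subsampled per 3-subset with a keep
probability, giving non-dense inputs whose members are still consistent
with the source; and ultrametric distance matrices `d(i,j) = 2·h_T(i,j)`
with optional symmetric Gaussian noise (sd in the same branch-length units,
default 0, floored at 0.01) feeding the distance rule the way an external
distance estimate would.  What the generators do **not** emulate: sequence
evolution and distance estimation error structure (noise here is i.i.d.
Gaussian, real distance noise is correlated along the tree), taxon numbers
beyond a few dozen, and biased triplet loss — so passing tests demonstrate
correctness of the combinatorics and the end-to-end guarantee, not
robustness to realistic inference error.

Default sizes in tests and the acceptance script (4–8 leaves, up to 3
reticulations, 30–100 replicates) are chosen so each randomized suite
completes in seconds to a few minutes while still exercising every branch
of the pipeline, including nested SN recursion and patching.

## Known limitations

- Reticulation count and level are heuristic upper bounds; `slow` mode is
  exponential in the number of criteria ties.
- The patching step can be generous on inputs whose conflicts are dense
  and scattered (each round spends one reticulation on one cherry group).
- The exact consistency decision enumerates paths; beyond roughly a dozen
  reticulations in one biconnected component it would need the flow-based
  formulation instead.
- eNewick output uses the `#H<k>`-tag dialect without branch lengths; other
  dialects (branch lengths on reticulation edges, per-parent probabilities)
  are not parsed.
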