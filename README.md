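# tripnet

Construct rooted phylogenetic networks with few reticulation nodes from an
**arbitrary** set of rooted triplets — the input does not have to be dense
(one triplet per three taxa) and may even contain conflicting triplets.

## The problem

A rooted triplet `ij|k` is the smallest informative statement about rooted
evolutionary history: taxa *i* and *j* are more closely related to each other
than either is to *k*.  Triplets are routinely inferred from distance
matrices, gene trees, or quartet/triplet inference on sequence data.  When
the triplets are compatible with a tree, Aho's classical BUILD recursion
finds that tree in polynomial time.  When they are not — because of
hybridization, recombination, lateral transfer, or simply estimation noise —
the natural target is a *rooted phylogenetic network*: a rooted DAG in which
reticulation nodes (indegree 2, outdegree 1) absorb the conflicting signal.
A triplet `ij|k` is *consistent* with a network *N* when *N* contains a
subdivision of it: nodes *u*, *v* with pairwise internally node-disjoint
paths *u*→*i*, *u*→*j*, *v*→*u*, *v*→*k*.  Finding a network with the
minimum number of reticulation nodes consistent with a triplet set is
NP-hard, and earlier constructive methods require dense inputs; this package
implements a heuristic that accepts any triplet set and returns a network
consistent with **all** of it, keeping the reticulation count small.

## The method

The central object is the *height function*.  For a tree *T* with longest
root path `l_T`, `h_T(i,j) = l_T − depth(lca(i,j))`; `ij|k` is consistent
with *T* iff `h_T(i,j) < h_T(i,k)` or `h_T(i,j) < h_T(j,k)`.  For a triplet
set τ the analogue is obtained from the *pair digraph* `G_τ` on unordered
taxon pairs, with arcs `ij → ik` and `ij → jk` for every `ij|k ∈ τ`:

1. **Heights.**  If `G_τ` is cyclic (conflicting triplets), a deterministic
   feedback-arc heuristic removes a few arcs.  Layering the DAG by repeated
   sink-peeling yields the unique pointwise-maximal solution of the integer
   program `h(i,j)+1 ≤ h(i,k)`, `h(i,j)+1 ≤ h(j,k)`, `1 ≤ h ≤ s` at the
   minimal feasible ceiling `s`.
2. **HBUILD.**  Iteratively deleting the maximum-weight edge class of the
   height-weighted complete graph either reconstructs a tree realising *h*
   (done — return its binarization) or proves none exists.
3. **SN-decomposition.**  The taxa are partitioned into *SN-sets* (subsets
   no outside cherry reaches into) by the same edge-deletion process, and
   each SN-set is contracted to a single node with min-height weights.
4. **Reticulation leaves.**  While the contracted triplets admit no tree,
   three criteria (minimum outgoing height; degree among minimum-weight
   edges; number of nontrivial SN-sets after deletion) pick a node to set
   aside as a *reticulation leaf*.
5. **Reassembly.**  The surviving nodes form a tree; each reticulation leaf
   is re-inserted below a fresh reticulation node spanning the edge pair
   that keeps the most triplets consistent; contracted SN-sets are expanded
   by recursion; any still-inconsistent triplets are patched by extra
   reticulation edges between the offending cherry's pendant edges, so the
   final network is consistent with every input triplet by construction.

## Worked example

The 15-triplet set over `{i,…,o}` below admits no tree but is consistent
with a single-reticulation (level-1) network:

```sh
$ cat triplets.txt
i j l
j k i
k l j
k l i
n o m
l o k
j l o
m n l
m n j
n o k
m o i
j k n
i j o
i k m
i l n
$ tripnet decompose --triplets triplets.txt
SN partition: {i} {j} {k} {l} {m} {n,o}
R1 = ['k', 'l']
R2 = ['k', 'l']
R3 = ['l']
$ tripnet run --triplets triplets.txt --speed slow
((i,(j,(k,(l)#H1))),(#H1,(m,(n,o))));
```

The decomposition isolates the cherry `{n,o}` as the only nontrivial SN-set;
the selection criteria narrow the reticulation-leaf candidates from
`{k, l}` down to `l`; and the resulting eNewick network hangs `l` below a
reticulation node (`#H1` appears twice: once defining the hybrid node, once
as the second parent's stub).  The network has 1 reticulation node, is
level-1, and is consistent with all 15 input triplets — `tripnet check
--network net.enwk --triplets triplets.txt` reports `15/15 consistent
(1.000)`.

In Python the same run is:

```python
>>> from tripnet import parse_triplets, tripnet
>>> res = tripnet(parse_triplets(open("triplets.txt")), speed="slow", seed=0)
>>> res.n_reticulations, res.level, res.reticulation_order
(1, 1, ['l'])
```

Other entry points: `tripnet tcd` infers triplets from a PHYLIP distance
matrix (`ij|k` iff `D_ij < min(D_ik, D_jk)`), `tripnet build` / `tripnet
hbuild` run the tree constructions alone, and `tripnet simulate` generates
random trees/networks and (sub)samples of their consistent triplets.

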