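# partialdigest

Exact solvers for the **partial digest problem** (PDP, also known as the
turnpike problem): given the multiset *D* of all *n(n−1)/2* pairwise
distances between points on a line, reconstruct *every* point set *X*
with difference multiset *ΔX = D*.

The PDP is the computational core of restriction-site mapping by partial
digestion: a single restriction enzyme cuts a DNA molecule at every subset
of its recognition sites, so the observed fragment lengths are exactly the
pairwise distances among the cut positions plus the two molecule ends, and
recovering the site map means solving the PDP.  Solutions come in mirror
pairs — *X* and its reflection *{width − x}* produce the same distances —
and some instances have additional homometric solutions.

## Algorithms

All three solvers explore the same solution tree.  A node is a pair
*(X, D<sub>res</sub>)* of a partial point set and the residual distance
pool, with the invariant *D<sub>res</sub> = D \\ ΔX*.  The root places the
two extreme points, *X = {0, width}*; a node expands by realising the
largest residual distance *y = max(D<sub>res</sub>)* with a point at
coordinate *y* or *width − y*, keeping a candidate only if its distances to
all placed points are available in the pool (the bounding condition
*Δ(y, X) ⊆ D<sub>res</sub>*).

* **BBd** — the classical depth-first branch and bound ("place the largest
  unexplained distance").  Identical subproblems reached along different
  paths are re-explored in full.
* **BBb** — breadth-first, level by level.  Since *D<sub>res</sub>* is a
  function of *X*, two same-level nodes with equal *X* are identical
  subproblems; BBb keeps only one.  On coincidence-rich inputs this
  collapses exponentially many duplicate subtrees.
* **BBb2** — two-stage breadth-first.  BBb's frontier can itself grow to
  ~2<sup>n</sup> nodes; BBb2 runs BBb to a split level α, then expands each
  surviving level-α node to completion as an independent BBb search,
  bounding the resident nodes by 2<sup>α</sup> + 2<sup>n−α</sup>.  The
  split level minimising the worst-case memory score
  *n²(2<sup>α</sup> + 2<sup>n−α</sup>)* is computed exactly
  (`find_alpha_m`); it is ⌊n/2⌋ up to tie-breaking.

Also included: generators for uniform-random benchmark maps and for the
adversarial five-block (Zhang-style) worst-case family, an in-silico
partial digestion simulator (FASTA + recognition motif → PDP instance),
and plain-text I/O.  Search effort is instrumented as node counts and
frontier sizes, which are machine-independent, rather than seconds or
megabytes.

## Worked example

The classic 10-distance instance *D = {1,2,2,3,5,6,7,8,8,10}*:

```sh
$ printf '1 2 2 3\n5 6 7 8 8 10\n' > example.txt
$ pdp solve -a bbb2 -i example.txt --stats
0 2 3 8 10
0 2 7 8 10
# algorithm: bbb2
# complete: True
# total nodes expanded: 6
# peak frontier: 3
# dedup hits: 1
# level 0: 1 nodes
# level 1: 2 nodes
# level 2: 1 nodes
# level 3: 2 nodes
```

The two lines are the two reconstructed maps — mirror images of each other
about the midpoint of the 10-unit molecule.  The `dedup hits: 1` comment
records the duplicated subproblem *X = {0,2,8,10}* that breadth-first
search reached twice and expanded once; depth-first search (`-a bbd`)
expands it twice and reports the same solution set.

The same from Python:

```python
from partialdigest import DistanceMultiset, validate_instance, solve_bbb2

inst = validate_instance(DistanceMultiset([1, 2, 2, 3, 5, 6, 7, 8, 8, 10]))
print(solve_bbb2(inst).solutions)
# [(0, 2, 3, 8, 10), (0, 2, 7, 8, 10)]
```

Other subcommands: `pdp generate` (random or worst-case instances),
`pdp digest` (simulate a partial digestion of a FASTA sequence),
`pdp alpha` (print the memory-minimising split level — e.g. `pdp alpha
--n 8` prints `alpha_M = 4`).

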