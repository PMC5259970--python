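# Methods

## The model

A partial digestion of a linear molecule of length *W* with one
restriction enzyme is idealised as complete pairwise information: with
internal cut sites *s₁ < … < s_k*, the site map is
*X = {0, s₁, …, s_k, W}* (*n = k + 2* points) and the observed data are
the fragment-length multiset *D = ΔX* of all *n(n−1)/2* pairwise
distances.  The partial digest problem is the inverse: find every *X* with
*ΔX = D*.  The model assumes exact integer lengths, no missing or
spurious fragments, and correct multiplicities; noisy or approximate
matching is out of scope, and fractional input is rejected at parse time
rather than rescaled.

The problem is translation- and reflection-invariant, so solutions are
reported anchored at 0 and always include the mirror map
*{W − x : x ∈ X}*.  Instances whose size is not a triangular number, or
that contain non-positive distances, are rejected up front
(`validate_instance`); *n* is recovered from *n(n−1)/2 = |D|* with
integer square-root arithmetic so that multi-million-fragment sizes cannot
be mis-rounded.

## Search tree and solvers

Every solver works on the same tree.  A node is *(X, D_res)* with the
invariant *D_res = D \ ΔX* (provable by induction on the level; asserted
node-by-node when `check_invariants=True`).  The root is
*X = {0, W}*, *D_res = D \ {W}*.  Expansion takes the largest residual
distance *y = max(D_res)*: one of the extreme points must realise it, so a
new point sits at coordinate *y* or at *W − y*.  A candidate survives only
if its distance to every placed point can be paid out of the residual pool
(*Δ(y, X) ⊆ D_res*); the child removes those distances.  A node with an
empty residual pool is a complete solution (this happens exactly when
*|X| = n*).  Degenerate case: when *y = W − y* the two branches are the
same state and a single child is generated.

**BBd** explores this tree depth-first with an explicit stack (maps with
thousands of sites would overflow the interpreter call stack), y-branch
before the *W − y* branch.  The branch order is a convention — it changes
the traversal trace, never the solution set.  BBd performs no subproblem
deduplication; its final solution list is deduplicated only at reporting
time, since duplicate subtrees yield duplicate copies of each solution.

**BBb** expands the tree level by level.  Because *D_res* is a function of
*X*, two same-level nodes with equal *X* are fully identical; each level
is deduplicated keyed on the ascending coordinate tuple alone.  The key
lookup uses a per-level hash table rather than a list scan — an
implementation-level change with identical observable behaviour.  When
invariant checking is on, the residual pools of a discarded duplicate and
its kept twin are compared before discarding.  Within-level processing
follows the insertion order of the previous level; tie-breaking does not
affect the reported set (asserted against BBd in tests).

**BBb2** bounds BBb's memory.  Stage 1 runs BBb to a split level α;
stage 2 expands each surviving level-α node to completion as an
independent BBb search, freeing each subtree's frontier before the next
starts.  Duplicates are removed within stage 1 and within each subtree but
not across subtrees, so the final solution list is deduplicated once more.
If the tree bottoms out before level α (small *n*), stage 1 simply runs to
exhaustion and stage 2 is empty.  The worst-case resident-node score
*M(α) = n²(2^α + 2^{n−α})* is minimised by an O(n) ascending scan over
α = 1…n with strict-improvement updates, so ties resolve to the smaller α
(n/2 for even *n*, (n−1)/2 for odd).  The scores are compared as exact big
integers: for *n* in the thousands, 2ⁿ is far beyond float range.

All solvers verify *ΔX = D* for every solution before reporting, report
solutions sorted lexicographically (making the three outputs
byte-comparable), and are deterministic given the input.

### Instrumentation and limits

Search effort is exposed as counts: nodes expanded per level and in total,
the largest frontier held at once, and dedup hits.  For BBb2 the peak
frontier counts the retained level-α frontier *plus* the current subtree's
frontier — the honest resident total.  Wall-clock and OS memory are
deliberately not part of the surface; they are hardware-bound.
Optional limits (`max_nodes`, `max_frontier`, `max_seconds`) raise
`LimitExceeded` carrying the partial result flagged incomplete.

## Synthetic instance generators

**Random maps (RD, average case).**  *X = {0} ∪* (n−1 distinct integers
uniform without replacement from 1…M); the instance is *ΔX*.  Benchmark
practice takes *M = n·q* with *q ∈ {10, 100, 1000, 10000}*; small *q*
crowds coordinates and produces the distance coincidences that make
deduplication pay.  The generator anchors at 0 (solver outputs are
0-anchored, making round-trip containment checks exact) and is
deterministic under a fixed seed.

**Five-block worst case (ZD).**  The classical adversarial construction
packs five arithmetic blocks of *n* coordinates with spacing ε into the
unit interval, two near each end and one in the middle; each middle
coordinate may independently be reflected to the other end without
changing the distance multiset locally, which is what forces depth-first
search into exponentially many identical subtrees.  Here the interval is
scaled to an integer width *W* (default 1000 per point,
*W = (5n+2)·1000* — for these instances difficulty is insensitive to the
coordinate scale, so the default simply matches the per-point density used
for the random family) with integer spacing ε (default the largest value
satisfying the disjointness bound 12·n·ε < W).  The middle-block split is
a seeded fair coin per element — any split realises the worst case.  The
generator verifies that the blocks plus the endpoints are pairwise
disjoint (|A| = 5n+2) and rejects parameters otherwise.

What these generators do **not** emulate: measurement noise, missing
fragments, multiplicities blurred by gel resolution, or circular
molecules.  Passing tests therefore demonstrate exact combinatorial
reconstruction, not robustness to experimental error.

## Digestion simulator

`digest_sequence` scans a FASTA sequence (via Biopython) for a literal
recognition motif — case-insensitive, overlapping occurrences counted, no
IUPAC degeneracy — and builds the PDP instance of the 0-based motif start
offsets plus the molecule ends.  The enzyme's cut offset within its
recognition site is exposed as a constant shift option; a uniform shift of
all internal sites changes no pairwise distance among them, so it matters
only for sites pushed onto or beyond the molecule ends, which are dropped.
The molecule is treated as linear (a circular chromosome's map is handled
as its linearisation), and sites exactly at a molecule end are rejected
rather than merged.  The fragment count always satisfies *N = n(n−1)/2*.

## Test-suite problem sizes

Exhaustive-oracle comparisons use maps of up to 6–8 points, where
brute-force subset enumeration is itself exact and fast; the worst-case
family is exercised at 17–27 points, large enough that depth-first search
expands tens of thousands of nodes while the deduplicating solvers expand
a few hundred, so the ordering assertions (BBb nodes < BBd nodes, BBb2
peak frontier ≤ BBb's) are comfortably away from degeneracy.  The
reference real instance is the 28-fragment TaqI digest of the 2009 bp
luciferase gene, solved in well under a second by all three algorithms.

## Known limitations

* Exact integer distances only; no error tolerance.
* Worst-case running time remains exponential — deduplication removes
  repeated subtrees, not the inherent ambiguity of homometric sets.
* Degenerate (IUPAC) motifs and enzyme databases are not supported; the
  double digest problem is out of scope.
* `max_seconds` is a cooperative wall-clock check, granular to node
  expansions.
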