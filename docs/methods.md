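# Methods

## The decoration model

The sample space at parameters (n, k) is the set S(n, k) of k-fold
decorated trees: a rooted binary tree T on leaves {1..n} with an
ancestral root edge, plus 2k subdivision points placed sequentially —
source p_i on any edge of the current tree, target p'_i on any edge of
the result, for i = 1..k.  The candidate network G is the subdivided
tree with the k arcs p_i → p'_i added.  Two facts anchor all counting:

* there are (2n−1)(2n)⋯(2n+2k−2) placement *sequences* per base tree,
  and every decorated tree arises from exactly k! of them (the pairs are
  distinguishable only by their positions, and any pair order produces
  the same final configuration);
* every *normal* network with k reticulations displays exactly 2^k
  distinct trees, so the normal decorated trees at (n, k) are exactly
  2^k copies (network, displayed tree) of each distinct normal network.

The second fact is what turns the census of decorated trees into the
network counts N_{n,k} and H_{n,k}; the census verifies the 2^k
divisibility on every run rather than assuming it.

Uniform sampling uses the same sequential process with uniform edge
choices, which is uniform over decorated trees by the k!-to-1 property;
base trees are uniform because each of the (2n−3)!! shapes has exactly
one leaf-insertion history.

## Classification conventions

Labels are assigned in the order cyclic → not-tree-child → shortcut →
normal, with normal split by the temporal test.  Two conventions are
worth stating because the definitions leave them open:

* **Parallel arcs.**  An arc placed alongside the tree edge p_i → p'_i
  creates a parallel pair.  Such a graph is acyclic, and the parallel
  edge is a shortcut (each copy is an alternative path for the other) —
  but the source vertex then has both out-edges pointing at a
  reticulation, so the graph already fails the tree-child test and is
  labeled `not_tree_child`.  `shortcuts()` still reports the edge.  Both
  labels sit in the non-normal coarse class, so no count that the
  package reports depends on this ordering.
* **Collinearity.**  Two reticulation edges are collinear when an
  endpoint of one reaches an endpoint of the other by a directed path of
  tree edges.  We require the two heads to be distinct reticulations and
  allow the empty path (a shared endpoint counts).  Were same-head pairs
  eligible, every k ≥ 1 network would be collinear and the implication
  "normal without collinear reticulation edges ⇒ temporal" would be
  vacuous; under our convention that implication is checked exhaustively
  for every n ≤ 5, k ≤ 2 with zero exceptions.

The temporal test merges each reticulation with its two parents
(union-find over reticulation edges), rejects if a tree edge joins two
members of one class, and topologically orders the quotient under tree
edges.  Among the valid orderings the one returned is deterministic
(classes released by smallest member id); every returned ranking is
re-validated literally, edge by edge, in the test suite.

## Induced subdivision tree and the ell statistic

The induced subdivision tree of a decorated tree is the minimal subtree
of the subdivided tree spanning the 2k points, with pass-through
vertices (non-subdivision vertices of degree 2 on a spanning path)
suppressed, so its vertices are subdivision points and branching
vertices only.  With ell = the number of subdivision points that are not
leaves of this subtree (a unary root counts), the subtree has exactly
4k − 2 − ell edges: it has 2k − ell leaves, ell unary vertices and
2k − ell − 1 binary vertices, and every non-root vertex contributes one
edge.  The identity is asserted on every decorated tree the census
visits and on random decorations at (n, k) = (20, 5); it matters because
ell ≥ 1 is forced whenever G is cyclic, which is the structural reason
cyclic placements are asymptotically negligible.

## Canonical codes and isomorphism

Networks are compared up to directed-graph isomorphism fixing each leaf
label (or erasing labels, for shape orbits).  Each vertex first gets its
*unfolding signature* — the canonical string of the tree obtained by
duplicating shared reticulation subDAGs.  The canonical code is then the
minimum DFS encoding over all child orderings that sort children by
signature, permuting ties exhaustively; a reticulation is expanded at
its first visit and back-referenced (`#j`) afterwards.  Minimising over
tie permutations makes the code sound — equal codes if and only if
isomorphic — because any isomorphism must match children with equal
unfolding signatures, so the candidate sets of the two graphs coincide.
The tie search is exponential in the number of equal-signature sibling
groups, which is negligible at census scales (k ≤ 2, n ≤ 6); the code is
not intended for large highly symmetric networks.  A networkx
isomorphism check serves as an independent oracle for the code in the
test suite, never as the implementation.

## Series and formulas

The series engine works over exact rationals only; square roots use the
term recurrence of s² = a, and the H₂ generating function is built three
independent ways (the case decomposition by the reticulation content of
the root bridgeless component, its solved form, and the partial-fraction
form in powers of 1/(1−r)).  The three expansions agreeing exactly to
order 12, with integral n![zⁿ] coefficients equal to the closed forms,
is the module's correctness argument; any transcription slip in one
route breaks the agreement.  Asymptotic predictions are evaluated in log
space (the right-hand sides overflow doubles near n ≈ 120) and compared
to exact counts through `log_ratio`, which exploits `math.log` on big
integers.

## Problem sizes and defaults

* Exhaustive census range: n ≤ 5 with k ≤ 2, n ≤ 6 with k ≤ 1 (and
  n ≤ 8 at k = 0).  The largest run, (5, 2), streams 623,700 decorated
  trees in well under a minute while retaining only the 9,240 normal
  outcomes; beyond this range the census refuses with a size estimate
  and points to the sampler, since |S(n,k)| grows like (2n)^{2k}(2n−3)!!.
* Monte Carlo: Wilson 95% score intervals (statsmodels) rather than Wald,
  because the normal-class proportion is extreme at both small n (near
  0) and large n (near 1).  Default trend grid n ∈ {5, 10, 20, 40, 80}
  at k = 2 with 20,000 samples per point: large enough that the climb of
  P(normal) dominates the interval widths, small enough to run in
  seconds.  The default CLI seed is fixed and documented (20250507) so
  every subcommand is reproducible without flags.
* Series truncation defaults to order 64; coefficients are exact big
  rationals, so the cap is a convenience, not a numerical limit.

## What the generator emulates — and what it does not

The sampler realises exactly the uniform decoration process the theory
analyses: uniform tree, uniform sequential arc placement.  It is *not* a
model of real reticulate evolution — real networks are not uniform over
decorated trees, have branch lengths, and empirical studies suggest
reticulation counts that grow with n — so passing tests say nothing
about inference from data.  What they do certify is the combinatorial
machinery itself: the counts, the classification, and the finite-size
face of the limit laws.

## Known limitations

* No closed forms for k ≥ 3 (none are known); the census and sampler
  are the only routes there.
* Classification accepts any ArcGraph-shaped DAG, but I/O is limited to
  the package's Newick/eNewick dialect (integer leaf labels, no branch
  lengths).
* The canonical code's tie search and the 2^k loop in `displayed_trees`
  assume small k; both are exact but not engineered for k beyond ~10.
* Monte Carlo estimates class *proportions*; it cannot estimate N_{n,k}
  itself at large n, which would require resolving counts at relative
  precision far beyond sampling reach.
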