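# arcnets

Phylogenetic networks from arc-decorated trees: exhaustive enumeration,
classification, exact counting, generating functions, and Monte Carlo
exploration.

## The problem

A rooted binary phylogenetic network on the leaf set {1, …, n} is a DAG
with labeled leaves (out-degree 0), tree vertices (in 1, out 2),
reticulation vertices (in 2, out 1), and a root of in-degree 0 and
out-degree 1 atop an ancestral root edge.  A natural way to build one is
to start from a rooted binary tree T and place k arcs between its edges:
for each pair i, subdivide an edge with a source point p_i, subdivide an
edge of the result with a target point p'_i, and finally add the arc
p_i → p'_i.  The object before arcs are added — the subdivided tree
together with the k point pairs — is a *k-fold decorated tree*; a tree
with its root edge has 2n−1 edges, so there are

    |S(T,k)| = (2n−1)(2n)⋯(2n+2k−2) / k!

decorated trees per base tree (the k! because pairs can be placed in any
order), and (2n−3)!! base trees.

The resulting graph can fail in interesting ways, giving a classification
hierarchy:

* **cyclic** — not a network at all;
* **not tree-child** — some vertex has no child that is a tree vertex or
  leaf;
* **shortcut** — tree-child, but some edge (u,v) has an alternative
  directed u→v path;
* **normal** — tree-child and shortcut-free;
* **hybridization (temporal)** — normal and admitting dates T(v) that
  increase strictly along tree edges and are equal across each
  reticulation and its two parents (hybrids need contemporaneous
  parents).

This package enumerates decorated trees exhaustively for small (n, k),
classifies every outcome, and deduplicates the normal networks up to
label-preserving isomorphism, producing the counts N_{n,k} (normal) and
H_{n,k} (hybridization).  Closed forms exist for k ≤ 2, e.g.

    H_{n,1} = N_{n,1} = [(2n+1)!! + 3(2n−1)!!]/2 − 3·n!·2^(n−1)
    H_{n,2} = (2n−1)!!(n³+9n²−16n−12) − 3·n!·2^n(n²−4)

and an exact-rational series engine expands the exponential generating
functions (r(z) = 1 − √(1−2z) for trees; H₁, H₂ as rational expressions
in r) as an independent route to the same numbers.  Asymptotically, for
fixed k (indeed for k = o(n^{1/3})),

    N_{n,k} ~ H_{n,k} ~ 2^(k−1)√2 / k! · (2/e)^n · n^(n+2k−1),

i.e. almost every arc placement that yields a network yields a normal —
even temporal — one.  A seeded Monte Carlo module makes that drift
visible at desk scale.

It is written for combinatorialists and phylogeneticists who want the
census numbers, the formulas, and the classifying machinery (tree-child /
shortcut / temporal tests, displayed trees, canonical forms, eNewick I/O)
behind one small API.

## Worked example

```python
>>> from arcnets import run_census, H2_exact
>>> res = run_census(4, 2)
>>> res.total, res.s_normal, res.distinct_normal, res.distinct_hyb
(37800, 192, 48, 36)
>>> res.shape_classes()
[12, 12, 24]
>>> H2_exact(4)
36
```

Of the 37,800 two-fold decorated trees on four leaves, 192 give a normal
network; since every normal network with k reticulations displays exactly
2^k trees, those 192 collapse to 192/4 = 48 distinct networks, of which
36 admit a temporal ordering — matching the closed form.  Ignoring leaf
labels, the 48 networks fall into three shapes with orbits of 12, 24 and
12.

The `examples/` directory holds short narrative scripts: an exhaustive
census, the closed-form/series/asymptotic tables, the sampling trend, and
eNewick classification.  A thin CLI wraps the same calls:

```
arcnets census --n 4 --k 2 --shapes
arcnets formulas --table H2 --n-from 4 --n-to 8 --asym
arcnets series --gf H2 --form partial_fractions --order 12
arcnets mc --n 40 --k 2 --samples 20000 --seed 1
arcnets classify --in network.enwk
```

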