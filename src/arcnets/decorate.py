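"""k-fold decoration of phylogenetic trees.

A k-fold decorated tree is a tree T together with 2k subdivision points
placed sequentially on its edges: for each pair i, a source point p_i
subdivides some edge of the current tree and a target point p'_i
subdivides some edge of the result (including the two half-edges just
created).  Adding an arc p_i -> p'_i for each pair later turns the
subdivided tree into a candidate network (see :mod:`arcnets.network`).

Counting: a tree with an ancestral root edge has 2n-1 edges, and each
placed point raises the edge count by one, so there are
(2n-1)(2n)...(2n+2k-2) placement sequences.  Every decorated tree is hit
by exactly k! of them (the pairs can be placed in any order), giving
(2n-1)(2n)...(2n+2k-2)/k! decorated trees per base tree.

Representation: a decoration stores, for each original edge of T
(identified by its head vertex), the ordered top-to-bottom tuple of point
ids on that edge.  Point 2i is the source and point 2i+1 the target of
pair i.  Two decorations are the same decorated tree iff their pairings
agree as *unordered* sets of (source-position, target-position) pairs,
which is exactly what :func:`decoration_key` captures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterator, List, Tuple

from .trees import PhyloTree, Seed, _rng

__all__ = [
    "DecoratedTree",
    "SubdivisionTree",
    "count_decorations",
    "enumerate_decorations",
    "sequence_multiplicities",
    "random_decoration",
    "decoration_key",
    "induced_subdivision_tree",
]

Position = Tuple[int, int]  # (edge head in T, rank along the edge, top first)
DecKey = FrozenSet[Tuple[Position, Position]]


@dataclass(frozen=True)
class DecoratedTree:
    """A base tree plus the placement of 2k paired subdivision points.

    ``points`` maps an edge head of the base tree to the tuple of point
    ids placed on that edge, ordered top to bottom.  Point ids 2i and
    2i+1 are the source and target of pair i.
    """

    base: PhyloTree
    k: int
    points: Dict[int, Tuple[int, ...]]

    def positions(self) -> Dict[int, Position]:
        """Map each point id to its (edge, rank) position."""
        pos: Dict[int, Position] = {}
        for head, pts in self.points.items():
            for rank, q in enumerate(pts):
                pos[q] = (head, rank)
        return pos

    def subdivided_children(self) -> List[List[int]]:
        """Adjacency of the subdivided tree T_k (no arcs added).

        Base-tree vertices keep their ids; the subdivision vertex for
        point q gets id ``base.num_vertices + q``.
        """
        base = self.base
        off = base.num_vertices
        children = [list(c) for c in base.children]
        children.extend([] for _ in range(2 * self.k))
        for head, pts in self.points.items():
            up = base.parent[head]
            chain = [off + q for q in pts]
            children[up][children[up].index(head)] = chain[0]
            for a, b in zip(chain, chain[1:]):
                children[a] = [b]
            children[chain[-1]] = [head]
        return children


@dataclass(frozen=True)
class SubdivisionTree:
    """Minimal subtree of T_k spanning the 2k subdivision vertices.

    ``ell`` is the number of subdivision vertices that are not leaves of
    this subtree (a unary root counts).  The subtree always has
    4k - 2 - ell edges.
    """

    root: int
    vertices: FrozenSet[int]
    edges: Tuple[Tuple[int, int], ...]
    ell: int


def count_decorations(n: int, k: int) -> int:
    """Number of k-fold decorated trees on a fixed base tree with n leaves.

    Exact integer (2n-1)(2n)...(2n+2k-2) / k!;  1 for k = 0.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    num = 1
    for j in range(2 * k):
        num *= 2 * n - 1 + j
    q, r = divmod(num, math.factorial(k))
    assert r == 0, "placement-sequence count must be divisible by k!"
    return q


def decoration_key(dec: DecoratedTree) -> DecKey:
    """Canonical identity of a decorated tree over a fixed base tree.

    The unordered set of (source-position, target-position) pairs.  Two
    placement sequences produce the same decorated tree iff their keys
    are equal; each key is reached by exactly k! sequences.
    """
    pos = dec.positions()
    return frozenset((pos[2 * i], pos[2 * i + 1]) for i in range(dec.k))


def _points_from_key(key: DecKey) -> Dict[int, Tuple[int, ...]]:
    """Rebuild a canonical ``points`` dict from a decoration key.

    Pair ids are assigned in sorted-key order, so enumeration output does
    not depend on the order in which placement sequences were explored.
    """
    per_edge: Dict[int, List[Tuple[int, int]]] = {}
    for i, (src, tgt) in enumerate(sorted(key)):
        per_edge.setdefault(src[0], []).append((src[1], 2 * i))
        per_edge.setdefault(tgt[0], []).append((tgt[1], 2 * i + 1))
    return {head: tuple(q for _, q in sorted(entries))
            for head, entries in per_edge.items()}


def _all_keys(tree: PhyloTree, k: int) -> Dict[DecKey, int]:
    """Map every decoration key to its number of placement sequences."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    heads = list(tree.edges())
    cfg: Dict[int, List[int]] = {h: [] for h in heads}
    out: Dict[DecKey, int] = {}
    npts = 2 * k

    def place(p: int) -> None:
        if p == npts:
            pos = {}
            for h in heads:
                for rank, q in enumerate(cfg[h]):
                    pos[q] = (h, rank)
            key = frozenset((pos[2 * i], pos[2 * i + 1]) for i in range(k))
            out[key] = out.get(key, 0) + 1
            return
        for h in heads:
            lst = cfg[h]
            for g in range(len(lst) + 1):
                lst.insert(g, p)
                place(p + 1)
                lst.pop(g)

    place(0)
    return out


def enumerate_decorations(tree: PhyloTree, k: int) -> Iterator[DecoratedTree]:
    """Yield every k-fold decorated tree on ``tree`` exactly once.

    Generates all placement sequences and deduplicates by
    :func:`decoration_key`; deterministic (sorted-key) iteration order.
    The number yielded equals ``count_decorations(tree.n, k)``.
    """
    for key in sorted(_all_keys(tree, k)):
        yield DecoratedTree(tree, k, _points_from_key(key))


def sequence_multiplicities(tree: PhyloTree, k: int) -> Dict[DecKey, int]:
    """Placement-sequence count per decorated tree (k! for every one)."""
    return _all_keys(tree, k)


def random_decoration(tree: PhyloTree, k: int, seed: Seed = None) -> DecoratedTree:
    """Draw a decorated tree uniformly from the decorations of ``tree``.

    Points are placed sequentially, each uniform over the current edges.
    Sequences are uniform and every decorated tree is reached by exactly
    k! of them, so decorated trees are uniform too.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    rng = _rng(seed)
    heads = list(tree.edges())
    cfg: Dict[int, List[int]] = {h: [] for h in heads}
    total = len(heads)
    for p in range(2 * k):
        slot = rng.randrange(total)
        for h in heads:
            m = len(cfg[h]) + 1
            if slot < m:
                cfg[h].insert(slot, p)
                break
            slot -= m
        total += 1
    return DecoratedTree(tree, k,
                         {h: tuple(lst) for h, lst in cfg.items() if lst})


def induced_subdivision_tree(dec: DecoratedTree) -> SubdivisionTree:
    """Minimal subtree of T_k containing the 2k subdivision vertices.

    Rooted at their most recent common ancestor.  ``ell`` counts the
    subdivision vertices with a child inside the subtree (the subtree
    root may be one); the edge count always equals 4k - 2 - ell.
    """
    if dec.k < 1:
        raise ValueError("induced subdivision tree is undefined for k = 0")
    children = dec.subdivided_children()
    nv = len(children)
    off = dec.base.num_vertices
    is_sub = [v >= off for v in range(nv)]
    total = 2 * dec.k

    # postorder counts of subdivision vertices per subtree
    cnt = [0] * nv
    order: List[int] = []
    stack = [0]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(children[v])
    for v in reversed(order):
        cnt[v] = int(is_sub[v]) + sum(cnt[c] for c in children[v])

    # MRCA: deepest vertex whose subtree holds all 2k points
    m = 0
    while True:
        nxt = next((c for c in children[m] if cnt[c] == total), None)
        if nxt is None:
            break
        m = nxt

    # the spanning subtree, with non-subdivision pass-through vertices
    # (exactly one child on a spanning path) suppressed: what remains are
    # the subdivision vertices and the branching vertices of T_k
    vertices = set()
    edges: List[Tuple[int, int]] = []
    ell = 0
    stack: List[Tuple[int, int]] = [(m, -1)]  # (vertex, nearest kept ancestor)
    while stack:
        v, up = stack.pop()
        live = [c for c in children[v] if cnt[c]]
        keep = is_sub[v] or len(live) >= 2
        if keep:
            vertices.add(v)
            if up >= 0:
                edges.append((up, v))
            if is_sub[v] and live:
                ell += 1
        for c in live:
            stack.append((c, v if keep else up))
    assert len(edges) == len(vertices) - 1
    return SubdivisionTree(m, frozenset(vertices), tuple(edges), ell)
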