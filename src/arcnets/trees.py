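"""Rooted binary phylogenetic trees on the leaf set {1, ..., n}.

Every tree carries an *ancestral root edge*: the root is a vertex of
in-degree 0 and out-degree 1 sitting above the topmost tree vertex.  This
edge is a first-class edge of the tree (it can be subdivided during
decoration), so a tree with n leaves has 2n - 1 edges and 2n vertices.

The number of such trees is the semifactorial (2n-3)!!, which is the basis
for the enumeration and the uniform sampler: leaf j+1 attaches to any of
the 2j - 1 edges of a tree on j leaves, giving 1 * 3 * ... * (2n-3)
shapes in total.
"""

from __future__ import annotations

import math
import random
from typing import Iterator, List, Sequence, Union

__all__ = [
    "PhyloTree",
    "NewickError",
    "count_trees",
    "enumerate_trees",
    "random_tree",
    "parse_newick",
    "write_newick",
]

Seed = Union[int, random.Random, None]


def _rng(seed: Seed) -> random.Random:
    if isinstance(seed, random.Random):
        return seed
    return random.Random(seed)


class PhyloTree:
    """A rooted binary leaf-labeled tree with an ancestral root edge.

    Vertices are opaque contiguous integers in construction order; vertex 0
    is always the root (in-degree 0, out-degree 1).  Every non-root vertex
    is the head of exactly one edge, so edges are identified with their
    head vertex: the edge set is ``range(1, num_vertices)``.

    Equality and hashing go through :meth:`code`, a canonical form
    (recursively: a leaf is its label, an internal vertex the sorted pair
    of child codes), never through vertex identifiers.
    """

    __slots__ = ("n", "parent", "children", "labels", "_code")

    ROOT = 0

    def __init__(self, n: int, parent: List[int], children: List[List[int]],
                 labels: List[int]):
        self.n = n
        self.parent = parent
        self.children = children
        self.labels = labels  # labels[v] = leaf label, 0 for internal/root
        self._code: str | None = None

    # -- construction ---------------------------------------------------

    @classmethod
    def single_leaf(cls, label: int = 1) -> "PhyloTree":
        """The unique tree on one leaf: root edge plus the labeled leaf."""
        return cls(1, [-1, 0], [[1], []], [0, label])

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.n, list(self.parent),
                         [list(c) for c in self.children], list(self.labels))

    def insert_leaf(self, edge_head: int, label: int) -> None:
        """Attach a new leaf by subdividing the edge with head ``edge_head``.

        Mutates the tree in place; the new attachment vertex and the new
        leaf get the next two vertex ids.
        """
        if not 1 <= edge_head < len(self.parent):
            raise ValueError(f"no edge with head {edge_head}")
        mid = len(self.parent)
        leaf = mid + 1
        up = self.parent[edge_head]
        self.children[up][self.children[up].index(edge_head)] = mid
        self.parent.append(up)
        self.children.append([edge_head, leaf])
        self.parent.append(mid)
        self.children.append([])
        self.parent[edge_head] = mid
        self.labels.extend([0, label])
        self.n += 1
        self._code = None

    # -- basic structure ------------------------------------------------

    @property
    def num_vertices(self) -> int:
        return len(self.parent)

    @property
    def num_edges(self) -> int:
        return len(self.parent) - 1

    def edges(self) -> range:
        """Edge heads; the root edge is the one with head ``children[0][0]``."""
        return range(1, len(self.parent))

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def leaves(self) -> List[int]:
        return [v for v in range(len(self.parent)) if not self.children[v]]

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if self.parent[self.ROOT] != -1 or len(self.children[self.ROOT]) != 1:
            raise ValueError("root must have in-degree 0, out-degree 1")
        seen_labels = []
        for v in range(1, len(self.parent)):
            ch = self.children[v]
            if ch:
                if len(ch) != 2:
                    raise ValueError(f"internal vertex {v} has out-degree {len(ch)}")
                if self.labels[v]:
                    raise ValueError(f"internal vertex {v} carries a leaf label")
            else:
                seen_labels.append(self.labels[v])
            if v not in self.children[self.parent[v]]:
                raise ValueError(f"broken parent/child incidence at vertex {v}")
        if sorted(seen_labels) != list(range(1, self.n + 1)):
            raise ValueError(f"leaf labels {sorted(seen_labels)} are not 1..{self.n}")
        if self.num_edges != 2 * self.n - 1:
            raise ValueError("edge count is not 2n-1")

    # -- canonical form -------------------------------------------------

    def code(self) -> str:
        if self._code is None:
            children = self.children
            labels = self.labels

            def rec(v: int) -> str:
                if not children[v]:
                    return str(labels[v])
                parts = sorted(rec(c) for c in children[v])
                return "(" + ",".join(parts) + ")"

            self._code = rec(children[self.ROOT][0])
        return self._code

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self.code() == other.code()

    def __hash__(self) -> int:
        return hash(self.code())

    def __repr__(self) -> str:
        return f"PhyloTree(n={self.n}, {write_newick(self)!r})"


def count_trees(n: int) -> int:
    """Number of rooted binary phylogenetic trees on [n]: (2n-3)!!.

    Computed through the factorial identity
    (2n-3)!! = (2n-2)! / (2^(n-1) (n-1)!) in exact integer arithmetic,
    with the convention (-1)!! = 1 so that the count is 1 at n = 1.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    num = math.factorial(2 * n - 2)
    den = (1 << (n - 1)) * math.factorial(n - 1)
    q, r = divmod(num, den)
    assert r == 0
    return q


def enumerate_trees(n: int) -> Iterator[PhyloTree]:
    """Yield every tree on [n] exactly once, in deterministic order.

    Built by sequential leaf insertion: leaf j+1 subdivides each of the
    2j-1 edges of each tree on j leaves in turn.  Each shape arises from
    exactly one insertion history, so no deduplication is needed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")

    def rec(t: PhyloTree) -> Iterator[PhyloTree]:
        if t.n == n:
            yield t
            return
        for head in t.edges():
            t2 = t.copy()
            t2.insert_leaf(head, t.n + 1)
            yield from rec(t2)

    yield from rec(PhyloTree.single_leaf())


def random_tree(n: int, seed: Seed = None) -> PhyloTree:
    """Draw a tree uniformly from the (2n-3)!! trees on [n].

    Each leaf insertion picks one of the current 2j-1 edges uniformly;
    since every shape has a unique insertion history the result is uniform.
    Passing the same integer seed reproduces the same tree; a
    ``random.Random`` instance may be passed to share a stream.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = _rng(seed)
    t = PhyloTree.single_leaf()
    for j in range(1, n):
        # a tree on j leaves has 2j vertices; edge heads are 1 .. 2j-1
        t.insert_leaf(rng.randrange(1, 2 * j), j + 1)
    return t


# -- Newick I/O ----------------------------------------------------------
#
# Dialect: leaf labels are the integers 1..n, no branch lengths, trailing
# semicolon.  The ancestral root edge is implicit in serialization: the
# written string describes the subtree below the root edge.


class NewickError(ValueError):
    """Malformed Newick input; carries the offending position."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


def write_newick(tree: PhyloTree) -> str:
    children = tree.children
    labels = tree.labels

    def rec(v: int) -> str:
        if not children[v]:
            return str(labels[v])
        return "(" + ",".join(sorted(rec(c) for c in children[v])) + ")"

    return rec(children[tree.ROOT][0]) + ";"


def write_decorated(dec) -> str:
    """Debug dump of a decorated tree: Newick of the subdivided tree with
    inline tags ``[pN:src]`` / ``[pN:tgt]`` on subdivision vertices.

    Subdivision points along each edge are written as a chain of unary
    bracketed tags between the edge's endpoints, top to bottom.
    """
    base = dec.base
    children = base.children
    labels = base.labels

    def tag(q: int) -> str:
        return f"[p{q // 2 + 1}:{'src' if q % 2 == 0 else 'tgt'}]"

    def rec(v: int) -> str:
        if not children[v]:
            body = str(labels[v])
        else:
            body = "(" + ",".join(sorted(rec(c) for c in children[v])) + ")"
        for q in reversed(dec.points.get(v, ())):
            body = f"({body}){tag(q)}"
        return body

    return rec(children[base.ROOT][0]) + ";"


def parse_newick(text: str) -> PhyloTree:
    """Parse the dialect written by :func:`write_newick`.

    Raises :class:`NewickError` with a position on malformed input,
    duplicate labels, or a label set different from 1..n.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise NewickError("missing trailing semicolon", len(text))
    s = s[:-1]
    pos = 0

    def parse_node():
        nonlocal pos
        if pos >= len(s):
            raise NewickError("unexpected end of input", pos)
        if s[pos] == "(":
            pos += 1
            kids = [parse_node()]
            while pos < len(s) and s[pos] == ",":
                pos += 1
                kids.append(parse_node())
            if pos >= len(s) or s[pos] != ")":
                raise NewickError("expected ')'", pos)
            pos += 1
            if len(kids) != 2:
                raise NewickError(f"non-binary vertex with {len(kids)} children", pos)
            return kids
        start = pos
        while pos < len(s) and s[pos].isdigit():
            pos += 1
        if pos == start:
            raise NewickError(f"expected a leaf label, found {s[pos]!r}", pos)
        return int(s[start:pos])

    top = parse_node()
    if pos != len(s):
        raise NewickError(f"trailing characters {s[pos:]!r}", pos)

    parent: List[int] = [-1]
    children: List[List[int]] = [[]]
    labels: List[int] = [0]

    def build(node, up: int) -> int:
        v = len(parent)
        parent.append(up)
        children.append([])
        children[up].append(v)
        if isinstance(node, int):
            labels.append(node)
        else:
            labels.append(0)
            for kid in node:
                build(kid, v)
        return v

    build(top, 0)
    leaf_labels = sorted(l for l in labels if l)
    n = len(leaf_labels)
    if leaf_labels != list(range(1, n + 1)):
        raise NewickError(f"leaf labels {leaf_labels} are not 1..{n}", 0)
    tree = PhyloTree(n, parent, children, labels)
    tree.validate()
    return tree
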