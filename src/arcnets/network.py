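"""Candidate networks from decorated trees, and their classification.

Adding an arc p_i -> p'_i for each pair of a k-fold decorated tree gives a
directed multigraph G.  G may contain a directed cycle; when acyclic it is
a phylogenetic network in which each target point p'_i is a reticulation
vertex (in-degree 2, out-degree 1) and each source point p_i a tree vertex
(in-degree 1, out-degree 2).  The classifiers here decide where G falls in
the hierarchy

    cyclic  |  network but not tree-child  |  tree-child with a shortcut
            |  normal, not temporal        |  hybridization (temporal)

which refines the coarse partition into cyclic / non-normal / normal
decorated trees, with the normal class split by the temporal-ordering
(hybridization) test.

Graphs are plain adjacency lists over contiguous integer vertices; vertex
0 is the root.  Parallel edges are legal (an arc alongside the tree edge
between its endpoints); such a graph both carries a shortcut and fails
the tree-child condition, so it is never normal.
"""

from __future__ import annotations

import enum
import heapq
from itertools import permutations, product
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .decorate import DecoratedTree
from .trees import PhyloTree

__all__ = [
    "ArcGraph",
    "ClassLabel",
    "build_graph",
    "is_acyclic",
    "is_tree_child",
    "shortcuts",
    "is_normal",
    "classify",
    "temporal_ranking",
    "check_ranking",
    "collinear_pairs",
    "displayed_trees",
    "canonical_code",
    "write_enewick",
    "parse_enewick",
]


class ClassLabel(enum.Enum):
    """Mutually exclusive, exhaustive outcome of classifying G."""

    CYCLIC = "cyclic"
    NOT_TREE_CHILD = "not_tree_child"
    SHORTCUT = "shortcut"
    NORMAL_NOT_HYB = "normal_not_hyb"
    HYBRIDIZATION = "hybridization"

    @property
    def coarse(self) -> str:
        """The three-way partition: cyclic / not_normal / normal."""
        if self is ClassLabel.CYCLIC:
            return "cyclic"
        if self in (ClassLabel.NOT_TREE_CHILD, ClassLabel.SHORTCUT):
            return "not_normal"
        return "normal"

    @property
    def is_normal(self) -> bool:
        return self.coarse == "normal"


class ArcGraph:
    """Directed multigraph over contiguous integer vertices; root is 0.

    ``children[v]`` lists the heads of v's out-edges (duplicates encode
    parallel edges).  ``labels[v]`` is the leaf label (0 for non-leaves).
    """

    __slots__ = ("children", "labels", "_indeg")

    ROOT = 0

    def __init__(self, children: List[List[int]], labels: List[int]):
        self.children = children
        self.labels = labels
        self._indeg: Optional[List[int]] = None

    @property
    def num_vertices(self) -> int:
        return len(self.children)

    @property
    def n(self) -> int:
        return sum(1 for l in self.labels if l)

    def indegree(self) -> List[int]:
        if self._indeg is None:
            indeg = [0] * len(self.children)
            for ch in self.children:
                for c in ch:
                    indeg[c] += 1
            self._indeg = indeg
        return self._indeg

    def reticulations(self) -> List[int]:
        """Vertices of in-degree 2, in increasing id order."""
        return [v for v, d in enumerate(self.indegree()) if d == 2]

    def parents(self) -> List[List[int]]:
        par: List[List[int]] = [[] for _ in self.children]
        for u, ch in enumerate(self.children):
            for c in ch:
                par[c].append(u)
        return par

    def edges(self) -> List[Tuple[int, int]]:
        return [(u, v) for u, ch in enumerate(self.children) for v in ch]

    def is_tree_edge(self, u: int, v: int) -> bool:
        """An edge is a tree edge iff its head is not a reticulation."""
        return self.indegree()[v] < 2


def build_graph(dec: DecoratedTree) -> ArcGraph:
    """G of a decorated tree: the subdivided tree plus one arc per pair."""
    children = dec.subdivided_children()
    off = dec.base.num_vertices
    for i in range(dec.k):
        children[off + 2 * i].append(off + 2 * i + 1)
    labels = list(dec.base.labels) + [0] * (2 * dec.k)
    return ArcGraph(children, labels)


def _toposort(g: ArcGraph) -> Optional[List[int]]:
    indeg = list(g.indegree())
    order = [v for v, d in enumerate(indeg) if d == 0]
    i = 0
    while i < len(order):
        for c in g.children[order[i]]:
            indeg[c] -= 1
            if indeg[c] == 0:
                order.append(c)
        i += 1
    return order if len(order) == g.num_vertices else None


def is_acyclic(g: ArcGraph) -> bool:
    """True iff G has no directed cycle; then G is a phylogenetic network."""
    return _toposort(g) is not None


def _require_dag(g: ArcGraph) -> None:
    if not is_acyclic(g):
        raise ValueError("operation is undefined on a cyclic graph")


def is_tree_child(g: ArcGraph) -> bool:
    """Every non-leaf vertex has a child that is a tree vertex or leaf."""
    _require_dag(g)
    indeg = g.indegree()
    return all(any(indeg[c] < 2 for c in ch) for ch in g.children if ch)


def _shortcut_edges(g: ArcGraph) -> Set[Tuple[int, int]]:
    out: Set[Tuple[int, int]] = set()
    children = g.children
    for r in g.reticulations():
        for u in set(p for p, ch in enumerate(children) if r in ch):
            if children[u].count(r) > 1:
                out.add((u, r))
                continue
            # r reachable from u through some child other than r itself?
            stack = [c for c in children[u] if c != r]
            seen = set(stack)
            while stack:
                x = stack.pop()
                if x == r:
                    out.add((u, r))
                    break
                for c in children[x]:
                    if c not in seen:
                        seen.add(c)
                        stack.append(c)
    return out


def shortcuts(g: ArcGraph) -> Set[Tuple[int, int]]:
    """All edges (u, v) with an alternative directed u -> v path.

    Only reticulation edges can be shortcuts (an alternative path forces
    in-degree 2 at the head).  A parallel pair of edges counts: each copy
    is a shortcut via the other.
    """
    _require_dag(g)
    return _shortcut_edges(g)


def is_normal(g: ArcGraph) -> bool:
    """Tree-child and shortcut-free."""
    return is_tree_child(g) and not shortcuts(g)


def temporal_ranking(g: ArcGraph) -> Optional[Dict[int, int]]:
    """Integer dates T(v) witnessing temporality, or None.

    A ranking must increase strictly along tree edges and be constant on
    each reticulation vertex together with its two parents.  Vertices are
    merged into equivalence classes over all reticulation edges; the
    ranking exists iff no tree edge joins two vertices of one class and
    the quotient digraph of the classes under tree edges is acyclic.
    Among valid rankings the one chosen is deterministic: classes are
    released in order of their smallest vertex id.
    """
    _require_dag(g)
    return _ranking(g)


def _ranking(g: ArcGraph) -> Optional[Dict[int, int]]:
    nv = g.num_vertices
    parent = list(range(nv))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    indeg = g.indegree()
    for u, ch in enumerate(g.children):
        for v in ch:
            if indeg[v] == 2:
                ru, rv = find(u), find(v)
                if ru != rv:
                    parent[ru] = rv

    members: Dict[int, List[int]] = {}
    for v in range(nv):
        members.setdefault(find(v), []).append(v)
    sig = {root: min(vs) for root, vs in members.items()}

    qedges: Dict[int, Set[int]] = {root: set() for root in members}
    for u, ch in enumerate(g.children):
        for v in ch:
            if indeg[v] < 2:
                ru, rv = find(u), find(v)
                if ru == rv:
                    return None  # tree edge inside a contemporaneous class
                qedges[ru].add(rv)

    qin = {root: 0 for root in members}
    for outs in qedges.values():
        for t in outs:
            qin[t] += 1
    heap = [(sig[root], root) for root, d in qin.items() if d == 0]
    heapq.heapify(heap)
    date: Dict[int, int] = {}
    while heap:
        _, root = heapq.heappop(heap)
        date[root] = len(date)
        for t in qedges[root]:
            qin[t] -= 1
            if qin[t] == 0:
                heapq.heappush(heap, (sig[t], t))
    if len(date) != len(members):
        return None  # quotient is cyclic
    return {v: date[find(v)] for v in range(nv)}


def check_ranking(g: ArcGraph, ranking: Dict[int, int]) -> bool:
    """Literal re-check of the two temporal conditions, edge by edge."""
    indeg = g.indegree()
    parents = g.parents()
    for u, ch in enumerate(g.children):
        for v in ch:
            if indeg[v] < 2:
                if not ranking[u] < ranking[v]:
                    return False
    for v, d in enumerate(indeg):
        if d == 2:
            u, w = parents[v]
            if not ranking[u] == ranking[v] == ranking[w]:
                return False
    return True


def classify(g: ArcGraph) -> ClassLabel:
    """One label per graph; the partition the census tabulates."""
    if _toposort(g) is None:
        return ClassLabel.CYCLIC
    indeg = g.indegree()
    for ch in g.children:
        if ch and not any(indeg[c] < 2 for c in ch):
            return ClassLabel.NOT_TREE_CHILD
    if _shortcut_edges(g):
        return ClassLabel.SHORTCUT
    if _ranking(g) is not None:
        return ClassLabel.HYBRIDIZATION
    return ClassLabel.NORMAL_NOT_HYB


def collinear_pairs(g: ArcGraph) -> Set[FrozenSet[Tuple[int, int]]]:
    """Pairs of reticulation edges joined by a directed tree path.

    Eligible pairs have distinct head reticulations; a path of tree edges
    (possibly empty, i.e. a shared endpoint) from an endpoint of one edge
    to an endpoint of the other makes the pair collinear.
    """
    _require_dag(g)
    indeg = g.indegree()
    redges = [(u, v) for u, ch in enumerate(g.children)
              for v in set(ch) if indeg[v] == 2]
    # reachability along tree edges only (empty path included)
    nv = g.num_vertices
    reach: List[Set[int]] = [set() for _ in range(nv)]
    for v in (_toposort(g) or [])[::-1]:
        reach[v].add(v)
        for c in g.children[v]:
            if indeg[c] < 2:
                reach[v] |= reach[c]
    out: Set[FrozenSet[Tuple[int, int]]] = set()
    for i, e1 in enumerate(redges):
        for e2 in redges[i + 1:]:
            if e1[1] == e2[1]:
                continue
            if any(b in reach[a] or a in reach[b]
                   for a in e1 for b in e2):
                out.add(frozenset((e1, e2)))
    return out


# -- displayed trees -----------------------------------------------------


def displayed_trees(g: ArcGraph) -> List[PhyloTree]:
    """The distinct trees displayed by a normal network.

    For each reticulation delete one of its two incoming arcs, then
    iteratively suppress degree-2 vertices (the root keeps its in-0/out-1
    shape).  Over all 2^k deletion choices a normal network with k
    reticulations yields exactly 2^k distinct trees.
    """
    if not is_normal(g):
        raise ValueError("displayed_trees is only defined for normal networks")
    parents = g.parents()
    retics = g.reticulations()
    seen: Dict[str, PhyloTree] = {}
    for choice in product(range(2), repeat=len(retics)):
        children = [list(ch) for ch in g.children]
        for r, pick in zip(retics, choice):
            children[parents[r][pick]].remove(r)
        tree = _contract_to_tree(children, g.labels)
        seen.setdefault(tree.code(), tree)
    return list(seen.values())


def _contract_to_tree(children: List[List[int]], labels: List[int]) -> PhyloTree:
    """Suppress degree-2 vertices and rebuild a PhyloTree."""
    indeg = [0] * len(children)
    for ch in children:
        for c in ch:
            indeg[c] += 1

    def resolve(v: int) -> int:
        # skip down through in-1/out-1 vertices
        while indeg[v] == 1 and len(children[v]) == 1:
            v = children[v][0]
        return v

    parent: List[int] = [-1]
    out_children: List[List[int]] = [[]]
    out_labels: List[int] = [0]

    def build(v: int, up: int) -> None:
        v = resolve(v)
        w = len(parent)
        parent.append(up)
        out_children.append([])
        out_labels.append(labels[v])
        out_children[up].append(w)
        for c in children[v]:
            build(c, w)

    top = resolve(children[ArcGraph.ROOT][0])
    build(top, 0)
    n = sum(1 for l in out_labels if l)
    tree = PhyloTree(n, parent, out_children, out_labels)
    tree.validate()
    return tree


# -- canonical codes -----------------------------------------------------
#
# Isomorphism here means a directed-graph isomorphism fixing every leaf
# label (or ignoring labels, for shape comparison).  Each vertex first
# gets its "unfolding" signature -- the canonical form of the tree
# obtained by duplicating shared reticulation subgraphs -- as a plain
# string, so equal structures get equal signatures in any process.  The
# code is then the minimum DFS encoding over all child orderings that
# sort children by signature, with ties permuted exhaustively; shared
# reticulations are emitted once and back-referenced in first-visit
# order.  Minimising over the tie permutations is what makes the code
# sound (equal codes <=> isomorphic), not just a hash.


def _signatures(g: ArcGraph, labeled: bool) -> List[str]:
    sig: List[Optional[str]] = [None] * g.num_vertices

    def rec(v: int) -> str:
        s = sig[v]
        if s is None:
            if not g.children[v]:
                s = f"L{g.labels[v] if labeled else 0}"
            else:
                s = "(" + "|".join(sorted(rec(c) for c in g.children[v])) + ")"
            sig[v] = s
        return s

    rec(g.ROOT)
    return sig  # type: ignore[return-value]


def canonical_code(g: ArcGraph, labeled: bool = True) -> str:
    """Canonical string: equal iff graphs are isomorphic.

    With ``labeled`` the isomorphism must fix leaf labels; without, leaf
    labels are erased, comparing unlabeled shapes.
    """
    _require_dag(g)
    sig = _signatures(g, labeled)
    indeg = g.indegree()

    orderings: List[Sequence[Tuple[int, ...]]] = []
    choice_vertices: List[int] = []
    fixed: Dict[int, Tuple[int, ...]] = {}
    for v, ch in enumerate(g.children):
        if not ch:
            continue
        groups: Dict[str, List[int]] = {}
        for c in ch:
            groups.setdefault(sig[c], []).append(c)
        variants = [
            tuple(sum((list(p) for p in combo), []))
            for combo in product(*(
                sorted(set(permutations(groups[s]))) for s in sorted(groups)))
        ]
        if len(variants) == 1:
            fixed[v] = variants[0]
        else:
            choice_vertices.append(v)
            orderings.append(variants)

    def encode(order: Dict[int, Tuple[int, ...]]) -> Tuple[str, ...]:
        tokens: List[str] = []
        ridx: Dict[int, int] = {}

        def rec(v: int) -> None:
            if indeg[v] == 2:
                j = ridx.get(v)
                if j is not None:
                    tokens.append(f"#{j}")
                    return
                ridx[v] = len(ridx)
                tokens.append(f"H{ridx[v]}")
            if not g.children[v]:
                tokens.append(str(g.labels[v] if labeled else 0))
                return
            tokens.append("(")
            for c in order[v]:
                rec(c)
            tokens.append(")")

        rec(g.ROOT)
        return tuple(tokens)

    best: Optional[Tuple[str, ...]] = None
    for combo in product(*orderings):
        order = dict(fixed)
        order.update(zip(choice_vertices, combo))
        cand = encode(order)
        if best is None or cand < best:
            best = cand
    assert best is not None
    return ",".join(best)


# -- extended Newick -----------------------------------------------------


def write_enewick(g: ArcGraph) -> str:
    """Serialize an acyclic graph in extended Newick.

    Each reticulation vertex appears twice under a shared ``#Hj`` tag:
    expanded with its subtree at the first (deterministic) visit, as a
    bare reference afterwards.  Child order follows vertex signatures so
    equal graphs serialize identically.
    """
    _require_dag(g)
    sig = _signatures(g, labeled=True)
    indeg = g.indegree()
    ridx: Dict[int, int] = {}

    def rec(v: int) -> str:
        if indeg[v] == 2:
            if v in ridx:
                return f"#H{ridx[v]}"
            ridx[v] = len(ridx) + 1
            tag = f"#H{ridx[v]}"
        else:
            tag = ""
        if not g.children[v]:
            return f"{g.labels[v]}{tag}"
        inner = ",".join(rec(c) for c in sorted(g.children[v], key=lambda c: sig[c]))
        return f"({inner}){tag}"

    return rec(g.children[g.ROOT][0]) + ";"


def parse_enewick(text: str) -> ArcGraph:
    """Parse the eNewick dialect written by :func:`write_enewick`.

    Plain Newick (no ``#H`` tags) parses to a tree-shaped ArcGraph.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("missing trailing semicolon")
    s = s[:-1]
    pos = 0
    hybrids: Dict[str, int] = {}
    children: List[List[int]] = [[]]
    labels: List[int] = [0]

    def new_vertex(label: int = 0) -> int:
        children.append([])
        labels.append(label)
        return len(children) - 1

    def parse_node() -> int:
        nonlocal pos
        kids: List[int] = []
        if pos < len(s) and s[pos] == "(":
            pos += 1
            kids.append(parse_node())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                kids.append(parse_node())
            if pos >= len(s) or s[pos] != ")":
                raise ValueError(f"expected ')' at position {pos}")
            pos += 1
        start = pos
        while pos < len(s) and s[pos].isdigit():
            pos += 1
        label = int(s[start:pos]) if pos > start else 0
        tag = None
        if pos < len(s) and s[pos] == "#":
            start = pos
            pos += 1
            while pos < len(s) and (s[pos].isalnum()):
                pos += 1
            tag = s[start:pos]
        if tag is not None:
            v = hybrids.get(tag)
            if v is None:
                v = new_vertex(label)
                hybrids[tag] = v
            elif label:
                labels[v] = label
        else:
            if not kids and not label:
                raise ValueError(f"unlabeled leaf at position {pos}")
            v = new_vertex(label)
        children[v].extend(kids)
        return v

    top = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters {s[pos:]!r}")
    children[0].append(top)
    return ArcGraph(children, labels)
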