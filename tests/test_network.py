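"""Graph construction, classification, canonical codes, eNewick."""

import random

import pytest

from arcnets import decorate, network, trees
from arcnets.decorate import DecoratedTree
from arcnets.network import (ArcGraph, ClassLabel, build_graph, canonical_code,
                             check_ranking, classify, collinear_pairs,
                             displayed_trees, is_acyclic, is_tree_child,
                             parse_enewick, shortcuts, temporal_ranking,
                             write_enewick)


def _cherry():
    return trees.parse_newick("(1,2);")


def _leaf_edge(t, label):
    return next(v for v in t.edges() if t.labels[v] == label)


def test_build_graph_k0_is_the_tree():
    t = trees.parse_newick("((1,2),(3,4));")
    g = build_graph(DecoratedTree(t, 0, {}))
    assert g.children == t.children and is_acyclic(g)
    assert classify(g) is ClassLabel.HYBRIDIZATION  # a tree is temporal


def test_target_above_source_forces_cycle():
    t = _cherry()
    head = _leaf_edge(t, 1)
    # point 1 (target) placed above point 0 (source) on the same edge
    g = build_graph(DecoratedTree(t, 1, {head: (1, 0)}))
    assert not is_acyclic(g)
    assert classify(g) is ClassLabel.CYCLIC
    with pytest.raises(ValueError):
        is_tree_child(g)
    with pytest.raises(ValueError):
        shortcuts(g)
    with pytest.raises(ValueError):
        temporal_ranking(g)
    with pytest.raises(ValueError):
        canonical_code(g)


def test_parallel_arc_is_a_shortcut_edge_and_not_tree_child():
    t = _cherry()
    head = _leaf_edge(t, 1)
    # source directly above target: the arc runs parallel to the tree edge
    g = build_graph(DecoratedTree(t, 1, {head: (0, 1)}))
    assert is_acyclic(g)
    off = t.num_vertices
    assert (off, off + 1) in shortcuts(g)
    # both outgoing edges of the source point at the reticulation, so the
    # graph already fails the tree-child condition
    assert not is_tree_child(g)
    assert classify(g) is ClassLabel.NOT_TREE_CHILD
    assert classify(g).coarse == "not_normal"


def test_degree_invariants_exhaustive_41():
    """All 840 graphs at (4,1): sources in-1/out-2, targets in-2/out-1,
    root in-0/out-1, leaves out-0, exactly k reticulations."""
    count = 0
    for t in trees.enumerate_trees(4):
        off = t.num_vertices
        for d in decorate.enumerate_decorations(t, 1):
            g = build_graph(d)
            indeg = g.indegree()
            assert indeg[g.ROOT] == 0 and len(g.children[g.ROOT]) == 1
            assert indeg[off] == 1 and len(g.children[off]) == 2
            assert indeg[off + 1] == 2 and len(g.children[off + 1]) == 1
            assert g.reticulations() == [off + 1]
            for v in range(g.num_vertices):
                if g.labels[v]:
                    assert not g.children[v]
            count += 1
    assert count == 840


def test_classification_is_a_partition_41(census41):
    assert sum(census41.fine.values()) == census41.total == 840


def test_vertex_with_two_reticulation_children_is_not_tree_child():
    """Search (4,2) for a graph whose tree vertex has two reticulation
    children; it must be classified NOT_TREE_CHILD."""
    t = trees.parse_newick("((1,2),(3,4));")
    hit = False
    for d in decorate.enumerate_decorations(t, 2):
        g = build_graph(d)
        if not is_acyclic(g):
            continue
        indeg = g.indegree()
        if any(ch and all(indeg[c] == 2 for c in ch) for ch in g.children):
            assert classify(g) is ClassLabel.NOT_TREE_CHILD
            hit = True
    assert hit


def test_tree_has_ranking_and_no_shortcuts():
    t = trees.parse_newick("((1,2),(3,4));")
    g = build_graph(DecoratedTree(t, 0, {}))
    assert shortcuts(g) == set()
    rk = temporal_ranking(g)
    assert rk is not None and check_ranking(g, rk)
    assert collinear_pairs(g) == set()


def test_rankings_validate_literally(census42):
    """Every ranking returned over the 48 normal (4,2) networks satisfies
    the two temporal conditions when re-checked edge by edge."""
    successes = 0
    for g in census42.representatives.values():
        rk = temporal_ranking(g)
        if rk is not None:
            assert check_ranking(g, rk)
            successes += 1
    assert successes == 36


def test_no_collinear_pair_implies_ranking(small_censuses, census52):
    """Normal network without collinear reticulation edges is temporal;
    zero exceptions over the whole exhaustive range."""
    reps = [g for res in small_censuses.values()
            for g in res.representatives.values()]
    reps += list(census52.representatives.values())
    for g in reps:
        if not collinear_pairs(g):
            assert temporal_ranking(g) is not None


def test_collinear_pair_in_known_shape(census42):
    """The normal-but-not-temporal (4,2) networks all have collinear
    reticulation edges (the contrapositive witness)."""
    non_temporal = [g for code, g in census42.representatives.items()
                    if code not in census42.hyb_codes]
    assert len(non_temporal) == 12
    for g in non_temporal:
        assert collinear_pairs(g)


# -- displayed trees -----------------------------------------------------


def test_displayed_trees_counts(census41, census42):
    for res, k in ((census41, 1), (census42, 2)):
        for g in res.representatives.values():
            assert len(displayed_trees(g)) == 2 ** k


def test_base_tree_is_displayed():
    rng = random.Random(1)
    found = 0
    while found < 20:
        t = trees.random_tree(6, rng)
        d = decorate.random_decoration(t, 2, rng)
        g = build_graph(d)
        if classify(g).is_normal:
            codes = {dt.code() for dt in displayed_trees(g)}
            assert t.code() in codes
            found += 1


def test_displayed_trees_rejects_non_normal():
    t = _cherry()
    head = _leaf_edge(t, 1)
    g = build_graph(DecoratedTree(t, 1, {head: (0, 1)}))  # shortcut
    with pytest.raises(ValueError):
        displayed_trees(g)


# -- canonical codes -----------------------------------------------------


def test_canonical_code_invariant_under_vertex_renumbering(census42):
    g = next(iter(census42.representatives.values()))
    perm = list(range(g.num_vertices))
    random.Random(3).shuffle(perm[1:])  # keep the root at 0
    inv = {old: new for new, old in enumerate(perm)}
    children = [[] for _ in perm]
    labels = [0] * len(perm)
    for old, ch in enumerate(g.children):
        children[inv[old]] = [inv[c] for c in ch]
        labels[inv[old]] = g.labels[old]
    assert canonical_code(ArcGraph(children, labels)) == canonical_code(g)


def test_canonical_code_distinguishes_relabeled_leaves(census41):
    # swap two leaf labels of an asymmetric network: the code must change
    changed = 0
    for g in census41.representatives.values():
        labels = [{1: 2, 2: 1}.get(l, l) for l in g.labels]
        if canonical_code(ArcGraph(g.children, labels)) != canonical_code(g):
            changed += 1
    assert changed > 0


def test_canonical_code_agrees_with_networkx_isomorphism(census41):
    """Independent oracle: equal codes iff networkx finds a
    label-preserving isomorphism (sampled pairs from the (4,1) reps)."""
    nx = pytest.importorskip("networkx")

    def to_nx(g):
        G = nx.MultiDiGraph()
        for v in range(g.num_vertices):
            G.add_node(v, label=g.labels[v])
        for u, ch in enumerate(g.children):
            for c in ch:
                G.add_edge(u, c)
        return G

    reps = list(census41.representatives.values())[:12]
    nm = lambda a, b: a["label"] == b["label"]
    for i, g1 in enumerate(reps):
        for g2 in reps[i + 1:]:
            same_code = canonical_code(g1) == canonical_code(g2)
            same_iso = nx.is_isomorphic(to_nx(g1), to_nx(g2), node_match=nm)
            assert same_code == same_iso == False  # distinct reps


def test_eq6_double_counting_41():
    """The two decorated trees displaying the same k=1 network share a
    canonical code: 108 normal decorated trees, 54 codes."""
    codes = []
    for t in trees.enumerate_trees(4):
        for d in decorate.enumerate_decorations(t, 1):
            g = build_graph(d)
            if classify(g).is_normal:
                codes.append(canonical_code(g))
    assert len(codes) == 108 and len(set(codes)) == 54


# -- eNewick -------------------------------------------------------------


def test_enewick_tree_is_plain_newick():
    t = trees.parse_newick("((1,2),(3,4));")
    g = build_graph(DecoratedTree(t, 0, {}))
    assert write_enewick(g) == "((1,2),(3,4));"


def test_enewick_single_reticulation_tag(census41):
    g = next(iter(census41.representatives.values()))
    s = write_enewick(g)
    assert s.count("#H1") == 2 and "#H2" not in s


def test_enewick_roundtrip_preserves_code(census42):
    for code, g in census42.representatives.items():
        g2 = parse_enewick(write_enewick(g))
        assert canonical_code(g2) == code


def test_enewick_parse_rejects_garbage():
    with pytest.raises(ValueError):
        parse_enewick("((1,2)")
    with pytest.raises(ValueError):
        parse_enewick("((1,),2);")
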