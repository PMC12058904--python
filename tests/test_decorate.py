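"""Decoration: counting, enumeration, sampling, induced subdivision trees."""

import math
import random
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from arcnets import decorate, trees
from arcnets.decorate import (DecoratedTree, count_decorations, decoration_key,
                              enumerate_decorations, induced_subdivision_tree,
                              random_decoration, sequence_multiplicities)


@pytest.mark.parametrize("n,k,expected", [
    (4, 0, 1), (4, 1, 56), (4, 2, 2520), (5, 2, 5940), (1, 1, 2),
])
def test_count_decorations_values(n, k, expected):
    assert count_decorations(n, k) == expected


def test_count_decorations_domain_errors():
    with pytest.raises(ValueError):
        count_decorations(0, 1)
    with pytest.raises(ValueError):
        count_decorations(3, -1)


@pytest.mark.parametrize("k", [0, 1, 2])
def test_enumeration_count_matches_formula_per_tree(k):
    for t in trees.enumerate_trees(4):
        decs = list(enumerate_decorations(t, k))
        assert len(decs) == count_decorations(4, k)
        keys = {decoration_key(d) for d in decs}
        assert len(keys) == len(decs)


def test_enumeration_total_over_all_base_trees():
    total = sum(1 for t in trees.enumerate_trees(4)
                for _ in enumerate_decorations(t, 1))
    assert total == 56 * 15 == 840


def test_every_decorated_tree_reached_by_exactly_k_factorial_sequences():
    t = next(trees.enumerate_trees(4))
    for k in (1, 2):
        mult = sequence_multiplicities(t, k)
        assert set(mult.values()) == {math.factorial(k)}
        assert len(mult) == count_decorations(4, k)


def test_random_decoration_uniform_over_56_cells():
    """On a fixed 4-leaf tree with k=1 the 56 decorations are equally
    likely (chi-square on 56k draws, alpha = 0.001)."""
    t = trees.parse_newick("((1,2),(3,4));")
    rng = random.Random(11)
    counts = {}
    for _ in range(56000):
        key = decoration_key(random_decoration(t, 1, rng))
        counts[key] = counts.get(key, 0) + 1
    assert len(counts) == 56
    _, p = stats.chisquare(list(counts.values()))
    assert p > 0.001


def test_random_decoration_deterministic_and_k0_identity():
    t = trees.random_tree(6, seed=5)
    d1 = random_decoration(t, 3, seed=9)
    d2 = random_decoration(t, 3, seed=9)
    assert decoration_key(d1) == decoration_key(d2)
    d0 = random_decoration(t, 0, seed=9)
    assert d0.points == {} and d0.base is t


# -- induced subdivision tree -------------------------------------------


def test_subdivision_tree_cherry_configuration():
    """p and p' on the two child edges of a cherry: the subtree is the
    cherry vertex plus two subdivision leaves, ell = 0, 2 edges."""
    t = trees.parse_newick("(1,2);")
    # edge heads: 1 = top vertex; its children hold labels 1 and 2
    heads = [v for v in t.edges() if t.is_leaf(v)]
    d = DecoratedTree(t, 1, {heads[0]: (0,), heads[1]: (1,)})
    sub = induced_subdivision_tree(d)
    assert sub.ell == 0
    assert len(sub.edges) == 2 == 4 * 1 - 2 - sub.ell


def test_subdivision_tree_chain_configuration():
    """p' directly below p on one edge: the subtree is the single edge
    p -> p', ell = 1 (the unary root p is a subdivision vertex)."""
    t = trees.parse_newick("(1,2);")
    head = next(v for v in t.edges() if t.is_leaf(v))
    d = DecoratedTree(t, 1, {head: (0, 1)})
    sub = induced_subdivision_tree(d)
    assert sub.ell == 1
    assert len(sub.edges) == 1 == 4 * 1 - 2 - sub.ell


def test_subdivision_tree_undefined_for_k0():
    t = trees.parse_newick("(1,2);")
    with pytest.raises(ValueError):
        induced_subdivision_tree(DecoratedTree(t, 0, {}))


@pytest.mark.parametrize("n,k", [(3, 1), (3, 2), (4, 1), (4, 2)])
def test_edge_identity_exhaustive(n, k):
    """Every decorated tree satisfies edges = 4k - 2 - ell."""
    for t in trees.enumerate_trees(n):
        for d in enumerate_decorations(t, k):
            sub = induced_subdivision_tree(d)
            assert len(sub.edges) == 4 * k - 2 - sub.ell
            assert len(sub.vertices) == len(sub.edges) + 1


def test_edge_identity_random_large():
    rng = random.Random(2024)
    for _ in range(2000):
        t = trees.random_tree(20, rng)
        d = random_decoration(t, 5, rng)
        sub = induced_subdivision_tree(d)
        assert len(sub.edges) == 4 * 5 - 2 - sub.ell


def test_subdivision_leaves_are_subdivision_vertices():
    rng = random.Random(77)
    for _ in range(200):
        t = trees.random_tree(10, rng)
        d = random_decoration(t, 3, rng)
        sub = induced_subdivision_tree(d)
        off = t.num_vertices
        with_child = {a for a, _ in sub.edges}
        for v in sub.vertices - with_child:
            assert v >= off  # every leaf of the subtree is a subdivision vertex


def test_decoration_count_approaches_power_regime():
    """count_decorations(n,k) / ((2n)^{2k}/k!) is 1 + O(k^2/n) when k
    grows like n^(1/4)."""
    for n in (10**3, 10**4, 10**5, 10**6):
        k = int(round(n ** 0.25))
        ratio = Fraction(count_decorations(n, k) * math.factorial(k),
                         (2 * n) ** (2 * k))
        assert abs(float(ratio) - 1.0) <= 2.0 * k * k / n


@settings(deadline=None, derandomize=True, max_examples=25)
@given(n=st.integers(2, 15), k=st.integers(1, 5), seed=st.integers(0, 2**31 - 1))
def test_random_decoration_places_2k_points(n, k, seed):
    t = trees.random_tree(n, seed)
    d = random_decoration(t, k, seed + 1)
    pos = d.positions()
    assert sorted(pos) == list(range(2 * k))
    sub = induced_subdivision_tree(d)
    assert len(sub.edges) == 4 * k - 2 - sub.ell
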