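"""Exhaustive census of decorated trees for small (n, k).

Enumerates every k-fold decorated tree on [n], classifies its graph
(cyclic / not tree-child / shortcut / normal / hybridization), stratifies
by the number ell of non-leaf subdivision vertices of the induced
subdivision tree, and deduplicates the normal outcomes by label-preserving
isomorphism.  The distinct normal and hybridization counts are the
N_{n,k} and H_{n,k} the closed forms predict, and the double-counting
identity |S_no| = 2^k N_{n,k} (every normal network with k reticulations
displays exactly 2^k trees) holds on every run.

The pipeline streams: only canonical codes (plus one representative graph
per code) of the comparatively rare normal outcomes are kept, so the
623,700 decorated trees of (n, k) = (5, 2) need only the memory of their
9,240 normal members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from . import decorate, network, trees
from .network import ArcGraph, ClassLabel

__all__ = ["CensusResult", "run_census", "shape_census", "census_supported"]

# exhaustive range kept small on purpose: |S(n,k)| grows like (2n)^(2k) r_n
_SUPPORTED = lambda n, k: (k == 0 and n <= 8) or (n <= 5 and k <= 2) or (n <= 6 and k <= 1)


def census_supported(n: int, k: int) -> bool:
    return n >= 1 and k >= 0 and _SUPPORTED(n, k)


@dataclass
class CensusResult:
    """Exact tabulation of one exhaustive (n, k) run."""

    n: int
    k: int
    total: int
    fine: Dict[ClassLabel, int]
    by_ell: Dict[int, int]
    fine_by_ell: Dict[Tuple[ClassLabel, int], int]
    distinct_normal: int
    distinct_hyb: int
    lemma_violations: int
    representatives: Dict[str, ArcGraph] = field(repr=False)
    hyb_codes: frozenset = field(repr=False)

    @property
    def s_cyclic(self) -> int:
        return self.fine.get(ClassLabel.CYCLIC, 0)

    @property
    def s_not_normal(self) -> int:
        return (self.fine.get(ClassLabel.NOT_TREE_CHILD, 0)
                + self.fine.get(ClassLabel.SHORTCUT, 0))

    @property
    def s_normal(self) -> int:
        return (self.fine.get(ClassLabel.NORMAL_NOT_HYB, 0)
                + self.fine.get(ClassLabel.HYBRIDIZATION, 0))

    @property
    def s_hyb(self) -> int:
        return self.fine.get(ClassLabel.HYBRIDIZATION, 0)

    def shape_classes(self) -> List[int]:
        """Orbit sizes when distinct normal networks are grouped by
        isomorphism ignoring leaf labels; sorted ascending."""
        orbits: Dict[str, int] = {}
        for g in self.representatives.values():
            shape = network.canonical_code(g, labeled=False)
            orbits[shape] = orbits.get(shape, 0) + 1
        return sorted(orbits.values())

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "k": self.k,
            "total": self.total,
            "fine": {lab.value: c for lab, c in sorted(self.fine.items(),
                                                       key=lambda x: x[0].value)},
            "coarse": {
                "cyclic": self.s_cyclic,
                "not_normal": self.s_not_normal,
                "normal": self.s_normal,
                "hybridization": self.s_hyb,
            },
            "by_ell": {str(e): c for e, c in sorted(self.by_ell.items())},
            "distinct_normal": self.distinct_normal,
            "distinct_hyb": self.distinct_hyb,
        }


def run_census(n: int, k: int) -> CensusResult:
    """Classify every k-fold decorated tree on [n] and deduplicate.

    Exact integers throughout.  Raises for (n, k) outside the supported
    exhaustive range, with a size estimate in the message.
    """
    if n < 1 or k < 0:
        raise ValueError("need n >= 1, k >= 0")
    if not _SUPPORTED(n, k):
        from .formulas import S_total_exact
        raise ValueError(
            f"census({n},{k}) is out of the supported exhaustive range "
            f"(would visit {S_total_exact(n, k)} decorated trees); "
            f"use the montecarlo module instead")

    fine: Dict[ClassLabel, int] = {}
    by_ell: Dict[int, int] = {}
    fine_by_ell: Dict[Tuple[ClassLabel, int], int] = {}
    reps: Dict[str, ArcGraph] = {}
    hyb_status: Dict[str, bool] = {}
    total = 0
    lemma_violations = 0

    for tree in trees.enumerate_trees(n):
        for dec in decorate.enumerate_decorations(tree, k):
            total += 1
            g = network.build_graph(dec)
            label = network.classify(g)
            fine[label] = fine.get(label, 0) + 1
            if k >= 1:
                sub = decorate.induced_subdivision_tree(dec)
                ell = sub.ell
                if len(sub.edges) != 4 * k - 2 - ell:
                    lemma_violations += 1
                by_ell[ell] = by_ell.get(ell, 0) + 1
                key = (label, ell)
                fine_by_ell[key] = fine_by_ell.get(key, 0) + 1
            if label.is_normal:
                code = network.canonical_code(g)
                is_hyb = label is ClassLabel.HYBRIDIZATION
                prev = hyb_status.setdefault(code, is_hyb)
                if prev != is_hyb:
                    raise AssertionError(
                        "temporal status must be isomorphism-invariant")
                reps.setdefault(code, g)

    result = CensusResult(
        n=n, k=k, total=total, fine=fine, by_ell=by_ell,
        fine_by_ell=fine_by_ell,
        distinct_normal=len(reps),
        distinct_hyb=sum(hyb_status.values()),
        lemma_violations=lemma_violations,
        representatives=reps,
        hyb_codes=frozenset(c for c, h in hyb_status.items() if h),
    )
    _check_invariants(result)
    return result


def _check_invariants(res: CensusResult) -> None:
    from .formulas import S_total_exact
    if res.total != S_total_exact(res.n, res.k):
        raise AssertionError("census total disagrees with the product formula")
    if res.s_normal != (1 << res.k) * res.distinct_normal:
        raise AssertionError("normal decorated trees are not 2^k per network")
    if res.s_hyb != (1 << res.k) * res.distinct_hyb:
        raise AssertionError("hybridization decorated trees are not 2^k per network")
    if res.lemma_violations:
        raise AssertionError("induced-subdivision-tree edge identity violated")


def shape_census(n: int, k: int) -> List[int]:
    """Orbit sizes of the unlabeled shapes of distinct normal networks."""
    return run_census(n, k).shape_classes()
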