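"""Seeded Monte Carlo estimates of class proportions.

Beyond the exhaustive range, the proportion of decorated trees whose
graph is cyclic, normal, or a hybridization network is estimated by
sampling: draw a uniform tree, decorate it uniformly, classify.  The
theory says P(normal) -> 1 as n grows with k fixed (and even for k
growing like o(n^(1/3))), and likewise for the hybridization fraction
among normal outcomes; the trend experiment makes those limits visible
at desk scale.

Intervals are 95% Wilson score intervals (statsmodels), which behave
sensibly for the extreme proportions that occur at both ends of the n
range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from statsmodels.stats.proportion import proportion_confint

from . import decorate, network, trees
from .network import ClassLabel
from .trees import Seed, _rng

__all__ = ["ProportionEstimate", "estimate", "trend_experiment"]


@dataclass(frozen=True)
class ProportionEstimate:
    """Per-class sample counts with 95% Wilson score intervals."""

    n: int
    k: int
    samples: int
    seed: Optional[int]
    counts: Dict[ClassLabel, int]

    def count(self, label: ClassLabel) -> int:
        return self.counts.get(label, 0)

    @property
    def normal_count(self) -> int:
        return (self.count(ClassLabel.NORMAL_NOT_HYB)
                + self.count(ClassLabel.HYBRIDIZATION))

    def proportion(self, label: ClassLabel) -> float:
        return self.count(label) / self.samples

    @property
    def p_normal(self) -> float:
        return self.normal_count / self.samples

    def interval(self, label: ClassLabel) -> Tuple[float, float]:
        return _wilson(self.count(label), self.samples)

    @property
    def normal_interval(self) -> Tuple[float, float]:
        return _wilson(self.normal_count, self.samples)

    @property
    def hyb_given_normal(self) -> Optional[float]:
        m = self.normal_count
        return self.count(ClassLabel.HYBRIDIZATION) / m if m else None

    @property
    def hyb_given_normal_interval(self) -> Optional[Tuple[float, float]]:
        m = self.normal_count
        return _wilson(self.count(ClassLabel.HYBRIDIZATION), m) if m else None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "k": self.k,
            "samples": self.samples,
            "seed": self.seed,
            "counts": {lab.value: c for lab, c in sorted(
                self.counts.items(), key=lambda x: x[0].value)},
            "p_normal": self.p_normal,
            "normal_interval": list(self.normal_interval),
            "p_hyb_given_normal": self.hyb_given_normal,
        }


def _wilson(count: int, nobs: int) -> Tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def estimate(n: int, k: int, samples: int, seed: Seed = None) -> ProportionEstimate:
    """Classify ``samples`` independent uniform decorated trees on [n]."""
    if samples < 1:
        raise ValueError("need at least one sample")
    rng = _rng(seed)
    counts: Dict[ClassLabel, int] = {}
    for _ in range(samples):
        tree = trees.random_tree(n, rng)
        dec = decorate.random_decoration(tree, k, rng)
        label = network.classify(network.build_graph(dec))
        counts[label] = counts.get(label, 0) + 1
    return ProportionEstimate(n=n, k=k, samples=samples,
                              seed=seed if isinstance(seed, int) else None,
                              counts=counts)


def trend_experiment(k: int, n_grid: Sequence[int], samples: int,
                     seed: Seed = None) -> List[ProportionEstimate]:
    """One estimate per n in ``n_grid`` (strictly increasing).

    Per-point substreams are derived from the master seed, so the whole
    table is reproducible from (k, n_grid, samples, seed).
    """
    if list(n_grid) != sorted(set(n_grid)):
        raise ValueError("n_grid must be strictly increasing")
    rng = _rng(seed)
    rows = []
    for n in n_grid:
        sub = rng.randrange(2**31)
        rows.append(estimate(n, k, samples, seed=sub))
    return rows
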