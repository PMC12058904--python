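"""Exact closed-form counts and log-space asymptotic approximations.

Notation: r_n = (2n-3)!! is the number of trees on [n]; N_{n,k} and
H_{n,k} are the numbers of normal, respectively hybridization, networks
with n leaves and k reticulation vertices.  Closed forms exist for k <= 2:

    H_{n,1} = N_{n,1} = [(2n+1)!! + 3(2n-1)!!]/2 - 3 n! 2^(n-1)
    H_{n,2} = (2n-1)!!(n^3 + 9n^2 - 16n - 12) - 3 n! 2^n (n^2 - 4)
    N_{n,2} = (2n-1)!!(3n-4)(n^2 + 11n + 6)/3 - n! 2^n (3n^2 + 2n - 8)

and for n -> infinity (k fixed, or growing as o(n^(1/3))):

    |S(n,k)| ~ 2^(2k-1) sqrt(2) / k! * (2/e)^n n^(n+2k-1)
    N_{n,k}  ~ H_{n,k} ~ 2^(k-1) sqrt(2) / k! * (2/e)^n n^(n+2k-1)
    N_{n,2} - H_{n,2} ~ (2 sqrt(2)/3) (2/e)^n n^(n+2)

All exact values use big-integer arithmetic; all asymptotic predictions
are held as natural logs, since the right-hand sides overflow doubles
already near n = 120.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .decorate import count_decorations
from .trees import count_trees

__all__ = [
    "semifactorial",
    "H1_exact",
    "H2_exact",
    "N2_exact",
    "S_total_exact",
    "AsymptoticValue",
    "S_asym",
    "N_asym",
    "NH_diff_asym",
    "log_ratio",
]

_LN2 = math.log(2.0)


def semifactorial(m: int) -> int:
    """m!! for odd m >= -1, with (-1)!! = 1.

    Uses (2j-1)!! = (2j)! / (2^j j!) exactly.
    """
    if m < -1 or m % 2 == 0:
        raise ValueError(f"semifactorial needs an odd m >= -1, got {m}")
    j = (m + 1) // 2
    q, r = divmod(math.factorial(2 * j), (1 << j) * math.factorial(j))
    assert r == 0
    return q


def H1_exact(n: int) -> int:
    """Hybridization (= normal) networks with one reticulation vertex."""
    if n < 3:
        raise ValueError(f"H1_exact needs n >= 3, got {n}")
    val2 = semifactorial(2 * n + 1) + 3 * semifactorial(2 * n - 1)
    q, r = divmod(val2, 2)
    assert r == 0
    return q - 3 * math.factorial(n) * (1 << (n - 1))


def H2_exact(n: int) -> int:
    """Hybridization networks with two reticulation vertices."""
    if n < 4:
        raise ValueError(f"H2_exact needs n >= 4, got {n}")
    return (semifactorial(2 * n - 1) * (n**3 + 9 * n**2 - 16 * n - 12)
            - 3 * math.factorial(n) * (1 << n) * (n**2 - 4))


def N2_exact(n: int) -> int:
    """Normal networks with two reticulation vertices."""
    if n < 4:
        raise ValueError(f"N2_exact needs n >= 4, got {n}")
    num = semifactorial(2 * n - 1) * (3 * n - 4) * (n**2 + 11 * n + 6)
    q, r = divmod(num, 3)
    assert r == 0, "the closed form must be divisible by 3"
    return q - math.factorial(n) * (1 << n) * (3 * n**2 + 2 * n - 8)


def S_total_exact(n: int, k: int) -> int:
    """Total number of k-fold decorated trees on [n] over all base trees."""
    return count_decorations(n, k) * count_trees(n)


@dataclass(frozen=True)
class AsymptoticValue:
    """An asymptotic prediction held as a natural log."""

    log_value: float

    @property
    def log10(self) -> float:
        return self.log_value / math.log(10.0)

    def render(self) -> str:
        """Big-float style rendering, e.g. '3.1416e+250'."""
        e = math.floor(self.log10)
        mant = 10.0 ** (self.log10 - e)
        return f"{mant:.6g}e{e:+d}"

    def __float__(self) -> float:
        return math.exp(self.log_value)


def _base_log(n: int, k: int) -> float:
    # log of (2/e)^n n^(n+2k-1) / k!
    return (n * (_LN2 - 1.0) + (n + 2 * k - 1) * math.log(n)
            - math.lgamma(k + 1))


def S_asym(n: int, k: int) -> AsymptoticValue:
    """Asymptotic total count of k-fold decorated trees on [n]."""
    if n < 1 or k < 0:
        raise ValueError("need n >= 1, k >= 0")
    return AsymptoticValue((2 * k - 1) * _LN2 + 0.5 * _LN2 + _base_log(n, k))


def N_asym(n: int, k: int) -> AsymptoticValue:
    """Asymptotic count of normal (and hybridization) networks."""
    if n < 1 or k < 0:
        raise ValueError("need n >= 1, k >= 0")
    return AsymptoticValue((k - 1) * _LN2 + 0.5 * _LN2 + _base_log(n, k))


def NH_diff_asym(n: int) -> AsymptoticValue:
    """Asymptotic count of normal-but-not-hybridization networks, k = 2."""
    if n < 1:
        raise ValueError("need n >= 1")
    return AsymptoticValue(math.log(2.0 * math.sqrt(2.0) / 3.0)
                           + n * (_LN2 - 1.0) + (n + 2) * math.log(n))


def log_ratio(exact: int, asym: AsymptoticValue) -> float:
    """log(exact / predicted); near 0 when the prediction is good.

    ``math.log`` takes arbitrary-precision integers, so this stays exact
    enough far beyond double-overflow scales.
    """
    if exact <= 0:
        raise ValueError("exact count must be positive")
    return math.log(exact) - asym.log_value
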