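"""Truncated power series with exact rational coefficients.

The exponential generating function of rooted binary trees is

    r(z) = sum_n (2n-3)!! z^n / n! = 1 - sqrt(1 - 2z),

and the hybridization-network EGFs for one and two reticulations are
rational expressions in r:

    H_1(z) = r^3 / (2 (1-r)^3)

    H_2(z) assembled from the bridgeless-component case decomposition
    (root component with 0, 1 or 2 reticulations), solvable in closed
    form or re-expanded in partial fractions in powers of 1/(1-r).

Everything here is exact rational arithmetic (fractions.Fraction); the
integrality of n! [z^n] on the counting series is itself a correctness
check, so no floating point is allowed in this module.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial
from typing import Sequence, Union

__all__ = [
    "RatSeries",
    "series_r",
    "H1_series",
    "H2_series",
    "egf_coeff",
]

Scalar = Union[int, Fraction]

DEFAULT_ORDER = 64


class RatSeries:
    """A power series in z truncated at a fixed order, exact rationals."""

    __slots__ = ("coef",)

    def __init__(self, coef: Sequence[Scalar]):
        self.coef = [Fraction(c) for c in coef]

    @classmethod
    def zero(cls, order: int) -> "RatSeries":
        return cls([0] * (order + 1))

    @classmethod
    def const(cls, c: Scalar, order: int) -> "RatSeries":
        s = cls.zero(order)
        s.coef[0] = Fraction(c)
        return s

    @property
    def order(self) -> int:
        return len(self.coef) - 1

    def __getitem__(self, n: int) -> Fraction:
        return self.coef[n]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RatSeries):
            return NotImplemented
        return self.coef == other.coef

    def __add__(self, other: "RatSeries") -> "RatSeries":
        return RatSeries([a + b for a, b in zip(self.coef, other.coef)])

    def __sub__(self, other: "RatSeries") -> "RatSeries":
        return RatSeries([a - b for a, b in zip(self.coef, other.coef)])

    def __neg__(self) -> "RatSeries":
        return RatSeries([-a for a in self.coef])

    def scale(self, c: Scalar) -> "RatSeries":
        c = Fraction(c)
        return RatSeries([c * a for a in self.coef])

    def __mul__(self, other: "RatSeries") -> "RatSeries":
        n = min(self.order, other.order)
        a, b = self.coef, other.coef
        out = [Fraction(0)] * (n + 1)
        for i in range(n + 1):
            if a[i]:
                for j in range(n + 1 - i):
                    out[i + j] += a[i] * b[j]
        return RatSeries(out)

    def inverse(self) -> "RatSeries":
        """Multiplicative inverse; requires a nonzero constant term."""
        if self.coef[0] == 0:
            raise ZeroDivisionError("series has no inverse: [z^0] = 0")
        n = self.order
        inv = [Fraction(0)] * (n + 1)
        inv[0] = 1 / self.coef[0]
        for m in range(1, n + 1):
            acc = Fraction(0)
            for j in range(1, m + 1):
                acc += self.coef[j] * inv[m - j]
            inv[m] = -acc / self.coef[0]
        return RatSeries(inv)

    def __truediv__(self, other: "RatSeries") -> "RatSeries":
        return self * other.inverse()

    def __pow__(self, e: int) -> "RatSeries":
        if e < 0:
            return self.inverse() ** (-e)
        out = RatSeries.const(1, self.order)
        base = self
        while e:
            if e & 1:
                out = out * base
            base = base * base
            e >>= 1
        return out

    def sqrt(self) -> "RatSeries":
        """Square root with [z^0] = 1, by the term recurrence of s^2 = a."""
        if self.coef[0] != 1:
            raise ValueError("sqrt requires [z^0] = 1")
        n = self.order
        s = [Fraction(0)] * (n + 1)
        s[0] = Fraction(1)
        for m in range(1, n + 1):
            acc = Fraction(0)
            for j in range(1, m):
                acc += s[j] * s[m - j]
            s[m] = (self.coef[m] - acc) / 2
        return RatSeries(s)


def series_r(order: int = DEFAULT_ORDER) -> RatSeries:
    """The tree EGF r(z) = 1 - sqrt(1 - 2z), truncated.

    n! [z^n] equals the tree count (2n-3)!! for every n up to the order.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    one_minus_2z = RatSeries.const(1, order)
    one_minus_2z.coef[1] = Fraction(-2)
    return RatSeries.const(1, order) - one_minus_2z.sqrt()


def H1_series(order: int = DEFAULT_ORDER) -> RatSeries:
    """EGF of hybridization networks with one reticulation vertex."""
    if order < 3:
        raise ValueError("order must be >= 3")
    r = series_r(order)
    u = RatSeries.const(1, order) - r
    return ((r ** 3) / (u ** 3)).scale(Fraction(1, 2))


_H2_FORMS = ("cases", "solved", "partial_fractions")

# partial-fraction coefficients of H_2 in powers of (1-r)^(-j), j = 1..7
_H2_PF = [Fraction(-15, 8), Fraction(9), Fraction(-123, 8), Fraction(9),
          Fraction(27, 8), Fraction(-6), Fraction(15, 8)]


def H2_series(order: int = DEFAULT_ORDER, form: str = "cases") -> RatSeries:
    """EGF of hybridization networks with two reticulation vertices.

    Three equivalent routes, kept separate so each checks the others:

    - ``cases``: sum the contributions of the root bridgeless component
      containing 0, 1 or 2 reticulations and solve the fixed-point
      relation H_2 = H_2 r + X by dividing by 1 - r;
    - ``solved``: the explicitly solved expression;
    - ``partial_fractions``: the seven-term expansion in (1-r)^(-j).
    """
    if order < 4:
        raise ValueError("order must be >= 4")
    if form not in _H2_FORMS:
        raise ValueError(f"form must be one of {_H2_FORMS}, got {form!r}")
    r = series_r(order)
    one = RatSeries.const(1, order)
    u = one - r
    h1 = ((r ** 3) / (u ** 3)).scale(Fraction(1, 2))

    if form == "cases":
        # root component with 0 reticulations (minus the H_2 r fixed point)
        x = (h1 * h1).scale(Fraction(1, 2))
        # root component with 1 reticulation
        x = x + h1 * ((r ** 2) / (u ** 3)) + (h1 * ((r ** 2) / (u ** 2))).scale(Fraction(1, 2))
        # root component with 2 reticulations
        x = x + ((r ** 4) / (u ** 4)).scale(Fraction(1, 2)) \
              + (r ** 4) / (u ** 5) \
              + ((r ** 5) / (u ** 5)).scale(Fraction(7, 2)) \
              + ((r ** 6) / (u ** 6)).scale(Fraction(5, 4))
        return x / u

    if form == "solved":
        return (h1 * h1) / u.scale(2) \
            + h1 * ((r ** 2) / (u ** 4)) \
            + (h1 * ((r ** 2) / (u ** 3))).scale(Fraction(1, 2)) \
            + ((r ** 4) / (u ** 5)).scale(Fraction(1, 2)) \
            + (r ** 4) / (u ** 6) \
            + ((r ** 5) / (u ** 6)).scale(Fraction(7, 2)) \
            + ((r ** 6) / (u ** 7)).scale(Fraction(5, 4))

    out = RatSeries.zero(order)
    for j, c in enumerate(_H2_PF, start=1):
        out = out + (u ** (-j)).scale(c)
    return out


def egf_coeff(s: RatSeries, n: int) -> Fraction:
    """n! [z^n] of a series: the labeled count it encodes at size n."""
    if n > s.order:
        raise ValueError(f"coefficient {n} beyond truncation order {s.order}")
    return s[n] * factorial(n)
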