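"""Partial ordinary and partial exponential Bell polynomials.

These combinatorial polynomials are the backbone of the finite-time
moment/coefficient algebra: the forward expansion of conditional moments in
Kramers-Moyal coefficients is a partial *ordinary* Bell series, and its
reciprocal inversion (the moment -> cumulant transformation) is a partial
*exponential* Bell series.

Everything here is exact: coefficients are Python integers, and the
polynomial evaluators are generic over any commutative ring supplied by the
caller (ints, fractions, floats, numpy arrays, sympy symbols, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Sequence

__all__ = [
    "Partition",
    "BellValue",
    "enumerate_partitions",
    "bell_terms",
    "ordinary_bell",
    "exponential_bell",
]


@dataclass(frozen=True)
class Partition:
    """A multiset partition of ``n`` into ``m`` parts.

    ``counts[r-1]`` is the multiplicity j_r of part size ``r``; the sequence
    has length exactly ``n - m + 1`` and satisfies

        sum_r j_r = m      and      sum_r r * j_r = n.
    """

    n: int
    m: int
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != self.n - self.m + 1:
            raise ValueError("counts must have length n - m + 1")
        if sum(self.counts) != self.m:
            raise ValueError("part multiplicities must sum to m")
        if sum(r * j for r, j in enumerate(self.counts, start=1)) != self.n:
            raise ValueError("weighted part multiplicities must sum to n")


@dataclass(frozen=True)
class BellValue:
    """One monomial of a partial Bell polynomial.

    ``coefficient`` multiplies the monomial ``prod_r x_r ** monomial[r-1]``
    over abstract slot symbols x_1 ... x_{n-m+1}.
    """

    coefficient: int
    monomial: tuple[int, ...]


def _check_args(n: int, m: int) -> None:
    if not (isinstance(n, int) and isinstance(m, int)):
        raise TypeError("n and m must be integers")
    if n < 1 or m < 1:
        raise ValueError(f"n and m must be positive, got n={n}, m={m}")
    if m > n:
        raise ValueError(f"require m <= n, got n={n}, m={m}")


def enumerate_partitions(n: int, m: int) -> list[Partition]:
    """All solutions (j_1, ..., j_{n-m+1}) of sum j_r = m, sum r*j_r = n.

    Order is canonical: lexicographically descending on the counts tuple,
    so the partition putting most weight on small parts comes first.
    """
    _check_args(n, m)
    length = n - m + 1
    out: list[Partition] = []

    def recurse(r: int, prefix: list[int], parts_left: int, weight_left: int) -> None:
        if r > length:
            if parts_left == 0 and weight_left == 0:
                out.append(Partition(n, m, tuple(prefix)))
            return
        # descending j_r gives descending lexicographic output order
        j_max = min(parts_left, weight_left // r)
        for j in range(j_max, -1, -1):
            recurse(r + 1, prefix + [j], parts_left - j, weight_left - r * j)

    recurse(1, [], m, n)
    return out


def bell_terms(n: int, m: int, kind: str = "ordinary") -> list[BellValue]:
    """Monomials of the partial Bell polynomial B_{n,m} with exact coefficients.

    kind="ordinary":     coefficient  m! / prod_r j_r!
    kind="exponential":  coefficient  n! / prod_r ( j_r! * (r!)**j_r )
    """
    if kind not in ("ordinary", "exponential"):
        raise ValueError(f"unknown kind {kind!r}")
    terms = []
    for part in enumerate_partitions(n, m):
        denom = 1
        for r, j in enumerate(part.counts, start=1):
            denom *= factorial(j)
            if kind == "exponential":
                denom *= factorial(r) ** j
        numer = factorial(m) if kind == "ordinary" else factorial(n)
        coeff, rem = divmod(numer, denom)
        assert rem == 0, "Bell coefficients are integers"
        terms.append(BellValue(coeff, part.counts))
    return terms


def _evaluate(n: int, m: int, inputs: Sequence, kind: str):
    if len(inputs) != n - m + 1:
        raise ValueError(
            f"B_{{{n},{m}}} takes {n - m + 1} inputs, got {len(inputs)}"
        )
    total = None
    for term in bell_terms(n, m, kind):
        prod = term.coefficient
        for x, j in zip(inputs, term.monomial):
            if j:
                prod = prod * x**j
        total = prod if total is None else total + prod
    return total


def ordinary_bell(n: int, m: int, inputs: Sequence):
    """Partial ordinary Bell polynomial B-hat_{n,m}(x_1, ..., x_{n-m+1})."""
    _check_args(n, m)
    return _evaluate(n, m, inputs, "ordinary")


def exponential_bell(n: int, m: int, inputs: Sequence):
    """Partial exponential Bell polynomial B_{n,m}(x_1, ..., x_{n-m+1}).

    Related to the ordinary variant by
    B-hat_{n,m}(x) = (m!/n!) * B_{n,m}(1! x_1, 2! x_2, ...).
    """
    _check_args(n, m)
    return _evaluate(n, m, inputs, "exponential")
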