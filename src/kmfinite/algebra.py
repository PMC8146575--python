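"""Exact algebra linking conditional moments and Kramers-Moyal coefficients.

For a Markov process sampled at finite lag tau, the n-th conditional moment
M_n(x', tau) = <(X_{t+tau} - X_t)^n | X_t = x'> is an exact polynomial in
tau and the Kramers-Moyal (KM) coefficients D_1 ... D_n,

    M_n = n! * sum_{k=1}^{n} (tau^k / k!) * Bhat_{n,k}(D_1, ..., D_{n-k+1}),

once all terms containing spatial derivatives of the D's (the Phi terms)
are neglected.  The reciprocal relation of the partial exponential Bell
polynomials inverts this exactly,

    D_n = (1 / (n! tau)) * sum_{k=1}^{n} (-1)^(k-1) (k-1)!
                            * B_{n,k}(M_1, ..., M_{n-k+1}),

which is precisely the moment -> cumulant transformation: n! tau D_n is the
n-th cumulant of the increment distribution.

This module provides both directions symbolically (exact rationals), a fast
numeric inversion usable bin-wise on arrays, and the operator-algebra
expansion that *does* produce the derivative (Phi) terms, for verification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb, factorial
from typing import Sequence

import numpy as np
import sympy as sp

from .bell import bell_terms, ordinary_bell

__all__ = [
    "MonomialTerm",
    "Expansion",
    "OperatorTerm",
    "OperatorExpansion",
    "moments_from_km",
    "km_from_moments",
    "forward_moments",
    "invert_numeric",
    "expand_with_derivatives",
    "phi_second_order",
    "bookkeeping_weight",
    "render",
    "parse",
]

MOMENTS_IN_D = "moments_in_D"
D_IN_MOMENTS = "D_in_moments"


# --------------------------------------------------------------------------
# polynomial expansions (derivative-free)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MonomialTerm:
    """coefficient * tau**tau_power * prod_p sym_p**exp  (sym = D or M)."""

    coefficient: Fraction
    tau_power: int
    exponents: tuple[tuple[int, int], ...]  # ((symbol index, exponent), ...)

    def index_weight(self) -> int:
        """Sum of symbol index times exponent (the grading weight)."""
        return sum(p * e for p, e in self.exponents)


@dataclass(frozen=True)
class Expansion:
    """A graded polynomial relating conditional moments and KM coefficients.

    direction = "moments_in_D": the expansion of M_n in tau and D_1..D_n.
    direction = "D_in_moments": the polynomial P_n(M_1..M_n) such that
    D_n = P_n / (n! tau); terms carry tau_power = 0.
    """

    order_n: int
    direction: str
    terms: tuple[MonomialTerm, ...]

    @property
    def symbol_family(self) -> str:
        return "D" if self.direction == MOMENTS_IN_D else "M"

    def as_sympy(self) -> sp.Expr:
        tau = sp.Symbol("tau", positive=True)
        expr = sum(
            (
                sp.Rational(t.coefficient.numerator, t.coefficient.denominator)
                * tau**t.tau_power
                * sp.prod(
                    [sp.Symbol(f"{self.symbol_family}{p}") ** e for p, e in t.exponents]
                )
                for t in self.terms
            ),
            sp.Integer(0),
        )
        if self.direction == D_IN_MOMENTS:
            expr = expr / (sp.factorial(self.order_n) * tau)
        return expr

    def coefficient_of(self, exponents: dict[int, int], tau_power: int = None):
        """Exact coefficient of a given monomial (0 if absent).

        For direction=D_in_moments the coefficient refers to the polynomial
        n! * tau * D_n, i.e. P_n, and tau_power is ignored.
        """
        want = tuple(sorted((p, e) for p, e in exponents.items() if e))
        for t in self.terms:
            if t.exponents == want and (
                tau_power is None or t.tau_power == tau_power
            ):
                return t.coefficient
        return Fraction(0)

    def render(self, format: str = "plain") -> str:
        return render(self, format=format)


def _canonical_sort(terms: list[MonomialTerm], order_n: int) -> tuple[MonomialTerm, ...]:
    def key(t: MonomialTerm):
        exp = dict(t.exponents)
        # descending lexicographic on (exp of highest index, ..., exp of index 1)
        vec = tuple(-exp.get(i, 0) for i in range(order_n, 0, -1))
        return (t.tau_power, vec)

    return tuple(sorted(terms, key=key))


def moments_from_km(n: int) -> Expansion:
    """Exact expansion of the n-th conditional moment in tau and D_1..D_n.

    M_n = n! sum_{k=1}^{n} tau^k/k! * Bhat_{n,k}(D_1, ..., D_{n-k+1}).
    """
    if not isinstance(n, int) or n < 1:
        raise ValueError(f"moment order must be a positive integer, got {n!r}")
    terms: list[MonomialTerm] = []
    for k in range(1, n + 1):
        pre = Fraction(factorial(n), factorial(k))
        for bv in bell_terms(n, k, "ordinary"):
            coeff = pre * bv.coefficient
            exps = tuple(
                (r, j) for r, j in enumerate(bv.monomial, start=1) if j
            )
            terms.append(MonomialTerm(coeff, k, exps))
    return Expansion(n, MOMENTS_IN_D, _canonical_sort(terms, n))


def km_from_moments(n: int) -> Expansion:
    """Exact inversion: D_n = P_n(M_1..M_n) / (n! tau).

    P_n = sum_{k=1}^{n} (-1)^(k-1) (k-1)! * B_{n,k}(M_1, ..., M_{n-k+1});
    P_n is the n-th cumulant of the increment law expressed in raw moments.
    """
    if not isinstance(n, int) or n < 1:
        raise ValueError(f"coefficient order must be a positive integer, got {n!r}")
    terms: list[MonomialTerm] = []
    for k in range(1, n + 1):
        pre = Fraction((-1) ** (k - 1) * factorial(k - 1))
        for bv in bell_terms(n, k, "exponential"):
            coeff = pre * bv.coefficient
            exps = tuple(
                (r, j) for r, j in enumerate(bv.monomial, start=1) if j
            )
            terms.append(MonomialTerm(coeff, 0, exps))
    return Expansion(n, D_IN_MOMENTS, _canonical_sort(terms, n))


# --------------------------------------------------------------------------
# numeric forward map and inversion
# --------------------------------------------------------------------------

def forward_moments(km_values: Sequence, tau: float, order: int | None = None):
    """Numeric forward map D_1..D_N -> M_1..M_N at lag tau.

    ``order`` truncates each moment's tau power series (None = full, i.e.
    all n terms for M_n).  Accepts scalars or numpy arrays per coefficient.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    D = [np.asarray(d, dtype=float) for d in km_values]
    out = []
    for n in range(1, len(D) + 1):
        kmax = n if order is None else min(order, n)
        total = 0.0
        for k in range(1, kmax + 1):
            pre = factorial(n) * tau**k / factorial(k)
            total = total + pre * ordinary_bell(n, k, D[: n - k + 1])
        out.append(total)
    return out


def invert_numeric(moment_values: Sequence, tau: float, order_m: int | str = "full"):
    """Recover D_1..D_N from conditional moments M_1..M_N at lag tau.

    order_m = "full" (or n per coefficient) applies the complete Bell
    inversion; an integer m truncates the forward series at tau^m before
    inverting recursively, reproducing the approximation hierarchy:
    m=1 gives the naive D_n = M_n/(n! tau), m=2 additionally removes the
    Bhat_{n,2} cross terms, and so on.  D_1 is identical at every order.

    Accepts scalars or numpy arrays (e.g. per-bin values); non-finite inputs
    propagate to non-finite outputs.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if order_m != "full" and (not isinstance(order_m, int) or order_m < 1):
        raise ValueError(f"order_m must be 'full' or a positive integer, got {order_m!r}")
    M = [np.asarray(m, dtype=float) for m in moment_values]
    D: list = []
    for n in range(1, len(M) + 1):
        e = n if order_m == "full" else min(order_m, n)
        corr = 0.0
        for k in range(2, e + 1):
            pre = factorial(n) * tau**k / factorial(k)
            corr = corr + pre * ordinary_bell(n, k, D[: n - k + 1])
        D.append((M[n - 1] - corr) / (factorial(n) * tau))
    return D


# --------------------------------------------------------------------------
# operator expansion with derivative (Phi) terms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OperatorTerm:
    """coefficient * tau**tau_power * prod D_p^(d)  over the listed factors.

    ``factors`` is a sorted multiset of (subscript p, derivative order d)
    pairs; d = 0 means the undifferentiated coefficient D_p.
    """

    coefficient: Fraction
    tau_power: int
    factors: tuple[tuple[int, int], ...]


def bookkeeping_weight(term: OperatorTerm) -> int:
    """Sum of subscripts minus sum of superscripts over the term's factors.

    For a valid term of the expansion of M_n this equals n.
    """
    return sum(p for p, _ in term.factors) - sum(d for _, d in term.factors)


@dataclass
class OperatorExpansion:
    """Result of the k-fold operator application, split term-by-term."""

    order_n: int
    order: int
    truncation_N: int
    max_deriv: int | None
    terms: tuple[OperatorTerm, ...]
    truncated: bool  # True if the max_deriv cap dropped any term

    @property
    def derivative_free(self) -> tuple[OperatorTerm, ...]:
        return tuple(t for t in self.terms if all(d == 0 for _, d in t.factors))

    @property
    def derivative_part(self) -> tuple[OperatorTerm, ...]:
        return tuple(t for t in self.terms if any(d > 0 for _, d in t.factors))

    def render(self, format: str = "plain") -> str:
        return render(self, format=format)


def _differentiate(state: dict, max_deriv: int | None):
    """One spatial derivative of sum_{terms} c * u^e * prod D_p^(d).

    u = (x - x'); derivatives act on u (lowering its power) or on one of the
    D factors (raising its superscript).  Returns (new_state, dropped_any).
    """
    out: dict = {}
    dropped = False
    for (u, fac), c in state.items():
        if u > 0:
            key = (u - 1, fac)
            out[key] = out.get(key, Fraction(0)) + c * u
        for i, (p, d) in enumerate(fac):
            if max_deriv is not None and d + 1 > max_deriv:
                dropped = True
                continue
            newfac = tuple(sorted(fac[:i] + ((p, d + 1),) + fac[i + 1:]))
            key = (u, newfac)
            out[key] = out.get(key, Fraction(0)) + c
    return {k: v for k, v in out.items() if v != 0}, dropped


def expand_with_derivatives(
    n: int,
    order: int,
    truncation_N: int,
    max_deriv: int | None = None,
) -> OperatorExpansion:
    """Full expansion of M_n at a given tau order, derivative terms included.

    The KM operator L = sum_p (-d/dx)^p D_p(x), truncated at p <= truncation_N,
    is applied k-fold (k = 1..order) to the delta initial condition; each
    integral against (x - x')^n is evaluated by integration by parts, i.e. by
    applying the adjoint sum_p D_p(x) d^p/dx^p to (x - x')^n and reading off
    the value at x = x'.  The zero-derivative terms reproduce the truncated
    Bell series exactly; the rest are the Phi correction terms.
    """
    if n < 1 or order < 1 or truncation_N < 1:
        raise ValueError("n, order and truncation_N must be positive")
    state: dict = {(n, ()): Fraction(1)}
    collected: list[OperatorTerm] = []
    truncated = False
    for k in range(1, order + 1):
        new: dict = {}
        for p in range(1, truncation_N + 1):
            tp = state
            for _ in range(p):
                tp, dropped = _differentiate(tp, max_deriv)
                truncated = truncated or dropped
            for (u, fac), c in tp.items():
                key = (u, tuple(sorted(fac + ((p, 0),))))
                new[key] = new.get(key, Fraction(0)) + c
        state = {k2: v for k2, v in new.items() if v != 0}
        for (u, fac), c in state.items():
            if u == 0:
                collected.append(OperatorTerm(c / factorial(k), k, fac))
    collected.sort(key=lambda t: (t.tau_power, t.factors))
    return OperatorExpansion(n, order, truncation_N, max_deriv, tuple(collected), truncated)


def phi_second_order(n: int, truncation_N: int) -> tuple[OperatorTerm, ...]:
    """Closed form of the second-order derivative terms Phi_n^[2].

    Phi_n^[2] = (tau^2/2) * sum_{s=0}^{n-1} sum_{m=s+1}^{N}
                n! * C(m, s) * D_{n-s}^{(m-s)} * D_m,
    with both subscripts restricted to <= truncation_N.
    """
    acc: dict[tuple[tuple[int, int], ...], Fraction] = {}
    for s in range(0, n):
        if not (1 <= n - s <= truncation_N):
            continue
        for m in range(s + 1, truncation_N + 1):
            fac = tuple(sorted(((m, 0), (n - s, m - s))))
            acc[fac] = acc.get(fac, Fraction(0)) + Fraction(factorial(n) * comb(m, s), 2)
    terms = [OperatorTerm(c, 2, fac) for fac, c in acc.items() if c != 0]
    terms.sort(key=lambda t: (t.tau_power, t.factors))
    return tuple(terms)


# --------------------------------------------------------------------------
# rendering and parsing
# --------------------------------------------------------------------------

def _fmt_coeff_plain(c: Fraction) -> str:
    if c.denominator == 1:
        return str(c.numerator)
    return f"{c.numerator}/{c.denominator}"


def _render_monomial(coefficient: Fraction, tau_power: int, symbols: list[str]) -> str:
    parts = []
    mag = abs(coefficient)
    if mag != 1 or (tau_power == 0 and not symbols):
        parts.append(_fmt_coeff_plain(mag))
    if tau_power == 1:
        parts.append("tau")
    elif tau_power > 1:
        parts.append(f"tau^{tau_power}")
    parts.extend(symbols)
    return "*".join(parts)


def _join_terms(rendered: list[tuple[bool, str]]) -> str:
    out = ""
    for i, (neg, body) in enumerate(rendered):
        if i == 0:
            out = ("-" if neg else "") + body
        else:
            out += (" - " if neg else " + ") + body
    return out


def render(obj, format: str = "plain") -> str:
    """Deterministic text form of an Expansion or OperatorExpansion.

    plain format is parseable back via :func:`parse`; latex is for display.
    """
    if format not in ("plain", "latex"):
        raise ValueError(f"unknown format {format!r}")
    if isinstance(obj, OperatorExpansion):
        terms = obj.terms
        if format == "latex":
            return sp.latex(_operator_sympy(terms))
        rendered = []
        for t in terms:
            syms = [
                f"D{p}" if d == 0 else f"D{p}^({d})" for p, d in t.factors
            ]
            rendered.append((t.coefficient < 0, _render_monomial(t.coefficient, t.tau_power, syms)))
        return _join_terms(rendered)
    if not isinstance(obj, Expansion):
        raise TypeError(f"cannot render {type(obj).__name__}")
    if format == "latex":
        return sp.latex(obj.as_sympy())
    fam = obj.symbol_family
    rendered = []
    for t in obj.terms:
        syms = []
        for p, e in t.exponents:
            syms.append(f"{fam}{p}" if e == 1 else f"{fam}{p}^{e}")
        rendered.append((t.coefficient < 0, _render_monomial(t.coefficient, t.tau_power, syms)))
    body = _join_terms(rendered)
    if obj.direction == D_IN_MOMENTS:
        nf = factorial(obj.order_n)
        denom = "tau" if nf == 1 else f"{nf}*tau"
        if len(obj.terms) == 1 and obj.terms[0].coefficient > 0:
            return f"{body}/{denom}" if nf == 1 else f"{body}/({denom})"
        return f"({body})/({denom})" if nf > 1 else f"({body})/{denom}"
    return body


def parse(text: str) -> Expansion:
    """Parse the plain render format back into an Expansion."""
    expr = sp.sympify(text.replace("^", "**"))
    tau = sp.Symbol("tau", positive=True)
    # rebuild tau with assumptions so fraction() cancels cleanly
    expr = expr.subs(sp.Symbol("tau"), tau)
    num, den = sp.fraction(sp.together(expr))
    syms = sorted(
        (s for s in expr.free_symbols if s.name != "tau"), key=lambda s: s.name
    )
    if not syms:
        raise ValueError("no moment/coefficient symbols found")
    fam = syms[0].name[0]
    if fam not in ("D", "M") or any(s.name[0] != fam for s in syms):
        raise ValueError("expected symbols from a single family D* or M*")
    indices = [int(s.name[1:]) for s in syms]
    if den.has(tau):
        # inverse direction: expr = P_n / (n! tau)
        c = sp.simplify(den / tau)
        if not c.is_Integer:
            raise ValueError("denominator must be n! * tau")
        n = 1
        while factorial(n) < int(c):
            n += 1
        if factorial(n) != int(c):
            raise ValueError(f"denominator {c} is not a factorial")
        n = max(n, max(indices))
        poly = sp.Poly(sp.expand(num), *[sp.Symbol(f"M{i}") for i in range(1, n + 1)])
        terms = []
        for mono, coeff in poly.terms():
            exps = tuple((i + 1, e) for i, e in enumerate(mono) if e)
            terms.append(MonomialTerm(Fraction(int(sp.nsimplify(coeff).p), int(sp.nsimplify(coeff).q)), 0, exps))
        return Expansion(n, D_IN_MOMENTS, _canonical_sort(terms, n))
    n = max(indices)
    gens = [tau] + [sp.Symbol(f"D{i}") for i in range(1, n + 1)]
    poly = sp.Poly(sp.expand(expr), *gens)
    terms = []
    for mono, coeff in poly.terms():
        q = sp.Rational(coeff)
        exps = tuple((i, e) for i, e in enumerate(mono[1:], start=1) if e)
        terms.append(MonomialTerm(Fraction(int(q.p), int(q.q)), int(mono[0]), exps))
    return Expansion(n, MOMENTS_IN_D, _canonical_sort(terms, n))


def _operator_sympy(terms: Sequence[OperatorTerm]) -> sp.Expr:
    tau = sp.Symbol("tau", positive=True)
    expr = sp.Integer(0)
    for t in terms:
        mono = sp.Rational(t.coefficient.numerator, t.coefficient.denominator) * tau**t.tau_power
        for p, d in t.factors:
            name = f"D_{p}" if d == 0 else f"D_{p}^{{({d})}}"
            mono *= sp.Symbol(name)
        expr += mono
    return expr
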