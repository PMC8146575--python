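"""Moment/coefficient expansions, inversion, cumulants, derivative terms."""

from fractions import Fraction
from math import comb, exp, factorial

import numpy as np
import pytest
import sympy as sp

from kmfinite.algebra import (
    D_IN_MOMENTS,
    MOMENTS_IN_D,
    Expansion,
    OperatorExpansion,
    bookkeeping_weight,
    expand_with_derivatives,
    forward_moments,
    invert_numeric,
    km_from_moments,
    moments_from_km,
    parse,
    phi_second_order,
    render,
)
from kmfinite.simulate import ou_conditional_moments


def terms_as_dict(expansion: Expansion) -> dict:
    return {(t.tau_power, t.exponents): t.coefficient for t in expansion.terms}


# Known expansions of the conditional moments in the KM coefficients
# (key: (tau power, ((index, exponent), ...)), value: integer coefficient).
FORWARD_EXPECTED = {
    1: {(1, ((1, 1),)): 1},
    2: {(1, ((2, 1),)): 2, (2, ((1, 2),)): 1},
    3: {(1, ((3, 1),)): 6, (2, ((1, 1), (2, 1))): 6, (3, ((1, 3),)): 1},
    4: {
        (1, ((4, 1),)): 24,
        (2, ((1, 1), (3, 1))): 24,
        (2, ((2, 2),)): 12,
        (3, ((1, 2), (2, 1))): 12,
        (4, ((1, 4),)): 1,
    },
    5: {
        (1, ((5, 1),)): 120,
        (2, ((1, 1), (4, 1))): 120,
        (2, ((2, 1), (3, 1))): 120,
        (3, ((1, 2), (3, 1))): 60,
        (3, ((1, 1), (2, 2))): 60,
        (4, ((1, 3), (2, 1))): 20,
        (5, ((1, 5),)): 1,
    },
    6: {
        (1, ((6, 1),)): 720,
        (2, ((1, 1), (5, 1))): 720,
        (2, ((2, 1), (4, 1))): 720,
        (2, ((3, 2),)): 360,
        (3, ((1, 2), (4, 1))): 360,
        (3, ((1, 1), (2, 1), (3, 1))): 720,
        (3, ((2, 3),)): 120,
        (4, ((1, 3), (3, 1))): 120,
        (4, ((1, 2), (2, 2))): 180,
        (5, ((1, 4), (2, 1))): 30,
        (6, ((1, 6),)): 1,
    },
}

# Known inversions: coefficients of P_n, where D_n = P_n(M_1..M_n) / (n! tau).
INVERSE_EXPECTED = {
    1: {((1, 1),): 1},
    2: {((2, 1),): 1, ((1, 2),): -1},
    3: {((3, 1),): 1, ((1, 1), (2, 1)): -3, ((1, 3),): 2},
    4: {
        ((4, 1),): 1,
        ((1, 1), (3, 1)): -4,
        ((2, 2),): -3,
        ((1, 2), (2, 1)): 12,
        ((1, 4),): -6,
    },
    5: {
        ((5, 1),): 1,
        ((1, 1), (4, 1)): -5,
        ((2, 1), (3, 1)): -10,
        ((1, 1), (2, 2)): 30,
        ((1, 2), (3, 1)): 20,
        ((1, 3), (2, 1)): -60,
        ((1, 5),): 24,
    },
    6: {
        ((6, 1),): 1,
        ((1, 1), (5, 1)): -6,
        ((3, 2),): -10,
        ((2, 1), (4, 1)): -15,
        ((2, 3),): 30,
        ((1, 1), (2, 1), (3, 1)): 120,
        ((1, 2), (4, 1)): 30,
        ((1, 2), (2, 2)): -270,
        ((1, 3), (3, 1)): -120,
        ((1, 4), (2, 1)): 360,
        ((1, 6),): -120,
    },
}


class TestForwardExpansion:
    @pytest.mark.parametrize("n", sorted(FORWARD_EXPECTED))
    def test_term_for_term(self, n):
        got = terms_as_dict(moments_from_km(n))
        assert got == {k: Fraction(v) for k, v in FORWARD_EXPECTED[n].items()}

    @pytest.mark.parametrize("n", range(1, 9))
    def test_grading(self, n):
        e = moments_from_km(n)
        for t in e.terms:
            assert 1 <= t.tau_power <= n
            assert t.index_weight() == n

    def test_rejects_nonpositive_order(self):
        with pytest.raises(ValueError):
            moments_from_km(0)


class TestInverseExpansion:
    @pytest.mark.parametrize("n", sorted(INVERSE_EXPECTED))
    def test_term_for_term(self, n):
        got = {t.exponents: t.coefficient for t in km_from_moments(n).terms}
        assert got == {k: Fraction(v) for k, v in INVERSE_EXPECTED[n].items()}

    @pytest.mark.parametrize("n", range(1, 9))
    def test_grading(self, n):
        for t in km_from_moments(n).terms:
            assert t.index_weight() == n

    def test_rejects_nonpositive_order(self):
        with pytest.raises(ValueError):
            km_from_moments(-2)


class TestRoundTrips:
    @pytest.mark.parametrize("n", range(1, 9))
    def test_symbolic_forward_then_inverse(self, n):
        # substituting M_k(D) into P_n(M)/(n! tau) must return exactly D_n
        subs = {
            sp.Symbol(f"M{k}"): moments_from_km(k).as_sympy() for k in range(1, n + 1)
        }
        expr = km_from_moments(n).as_sympy().subs(subs)
        assert sp.expand(expr - sp.Symbol(f"D{n}")) == 0

    def test_numeric_round_trip_machine_precision(self, rng):
        D_true = rng.uniform(-2, 2, size=6)
        for tau in (0.01, 0.1, 1.0):
            M = forward_moments(list(D_true), tau)
            D_back = invert_numeric(M, tau, "full")
            np.testing.assert_allclose(np.ravel(D_back), D_true, rtol=1e-10)

    def test_numeric_round_trip_on_arrays(self, rng):
        D_true = rng.uniform(-1, 1, size=(6, 8))
        M = forward_moments(list(D_true), 0.05)
        D_back = invert_numeric(M, 0.05, "full")
        np.testing.assert_allclose(np.vstack(D_back), D_true, rtol=1e-9)


def raw_moments(values, probs, n_max):
    return [sum(p * v**n for v, p in zip(values, probs)) for n in range(1, n_max + 1)]


def cumulants_by_recursion(mu, n_max):
    """kappa_n = mu_n - sum_{j=1}^{n-1} C(n-1, j-1) kappa_j mu_{n-j}."""
    kappa = []
    for n in range(1, n_max + 1):
        k = mu[n - 1] - sum(
            comb(n - 1, j - 1) * kappa[j - 1] * mu[n - j - 1] for j in range(1, n)
        )
        kappa.append(k)
    return kappa


class TestCumulantEquivalence:
    def test_inversion_yields_cumulants(self):
        # n! tau D_n evaluated at M_k = raw moments equals the n-th cumulant
        values = [Fraction(-1), Fraction(0), Fraction(2), Fraction(5)]
        probs = [Fraction(3, 10), Fraction(3, 10), Fraction(1, 5), Fraction(1, 5)]
        mu = raw_moments(values, probs, 8)
        kappa = cumulants_by_recursion(mu, 8)
        for n in range(1, 9):
            P = sum(
                t.coefficient
                * np.prod([mu[p - 1] ** e for p, e in t.exponents])
                for t in km_from_moments(n).terms
            )
            assert P == kappa[n - 1]


class TestTruncatedInversion:
    def test_odd_free_moments_give_exact_d2(self):
        d = 0.37
        tau = 0.2
        M = [0.0, 2 * tau * d, 0.0, 12 * tau**2 * d**2 / 2, 0.0, 0.0]
        for order in (1, 2, 3, "full"):
            D = invert_numeric(M[:2], tau, order)
            assert D[1] == pytest.approx(d, rel=1e-14)

    def test_first_order_is_naive_estimator(self, rng):
        M = list(rng.uniform(0.1, 1.0, size=5))
        tau = 0.3
        D = invert_numeric(M, tau, 1)
        for n in range(1, 6):
            assert D[n - 1] == pytest.approx(M[n - 1] / (factorial(n) * tau))

    def test_d1_identical_at_every_order(self, rng):
        M = list(rng.uniform(-0.5, 0.5, size=6))
        outs = [invert_numeric(M, 0.05, o)[0] for o in (1, 2, 4, "full")]
        assert len(set(float(v) for v in outs)) == 1

    def test_corrections_vanish_with_tau_on_ou_moments(self):
        # naive and corrected estimators agree in the tau -> 0 limit,
        # with the gap shrinking at least linearly in tau
        a, b, x0 = 1.0, 0.5, 0.8
        gaps = []
        for tau in (0.2, 0.1, 0.05, 0.025):
            M = list(ou_conditional_moments(x0, a, b, tau))
            d_first = invert_numeric(M, tau, 1)
            d_full = invert_numeric(M, tau, "full")
            gaps.append(abs(float(d_first[1] - d_full[1])))
        ratios = [gaps[i] / gaps[i + 1] for i in range(3)]
        assert all(r > 1.8 for r in ratios)

    def test_tau_must_be_positive(self):
        with pytest.raises(ValueError):
            invert_numeric([0.1], 0.0)

    def test_nonfinite_moments_propagate(self):
        D = invert_numeric([np.nan, 0.2], 0.1, "full")
        assert np.isnan(D[0]) and np.isnan(D[1])


# Third-order derivative corrections for the Fokker-Planck truncation
# (highest coefficient D2), as multiples of tau^3/6 for M1 and tau^3/3 for
# M2.  The M1 list is validated by the subscript/superscript bookkeeping
# rule; its last term is D1^(4) D2 D2 (weight +1), the unique completion
# consistent with that rule.
PHI3_M1_FP = {
    ((1, 0), (1, 0), (1, 2)): 1,
    ((1, 0), (1, 1), (1, 1)): 1,
    ((1, 1), (1, 2), (2, 0)): 3,
    ((1, 0), (1, 3), (2, 0)): 2,
    ((1, 0), (1, 2), (2, 1)): 1,
    ((1, 2), (2, 0), (2, 2)): 1,
    ((1, 3), (2, 0), (2, 1)): 2,
    ((1, 4), (2, 0), (2, 0)): 1,
}
PHI3_M2_FP = {
    ((1, 0), (1, 0), (1, 1)): 3,
    ((1, 0), (1, 2), (2, 0)): 7,
    ((1, 1), (1, 1), (2, 0)): 4,
    ((1, 0), (1, 1), (2, 1)): 3,
    ((1, 1), (2, 0), (2, 2)): 4,
    ((1, 2), (2, 0), (2, 1)): 7,
    ((1, 3), (2, 0), (2, 0)): 4,
    ((1, 0), (1, 0), (2, 2)): 1,
    ((1, 0), (2, 0), (2, 3)): 2,
    ((1, 0), (2, 1), (2, 2)): 1,
    ((2, 0), (2, 2), (2, 2)): 1,
    ((2, 0), (2, 1), (2, 3)): 2,
    ((2, 0), (2, 0), (2, 4)): 1,
}


class TestDerivativeExpansion:
    @pytest.mark.parametrize("N", [1, 2, 3, 4])
    def test_first_moment_second_order(self, N):
        # derivative part of M1 at order 2 is (tau^2/2) sum_m D_m D1^(m)
        exp = expand_with_derivatives(1, 2, N)
        deriv = {t.factors: t.coefficient for t in exp.derivative_part}
        expected = {
            tuple(sorted(((m, 0), (1, m)))): Fraction(1, 2) for m in range(1, N + 1)
        }
        assert deriv == expected

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    @pytest.mark.parametrize("N", [1, 2, 3, 4])
    def test_matches_phi2_closed_form(self, n, N):
        exp = expand_with_derivatives(n, 2, N)
        got = {t.factors: t.coefficient for t in exp.derivative_part}
        want = {t.factors: t.coefficient for t in phi_second_order(n, N)}
        assert got == want

    @pytest.mark.parametrize("n,order,N", [(1, 3, 2), (2, 3, 2), (3, 2, 4), (4, 3, 3)])
    def test_bookkeeping_rule(self, n, order, N):
        exp = expand_with_derivatives(n, order, N)
        for t in exp.terms:
            assert bookkeeping_weight(t) == n

    @pytest.mark.parametrize("n,order,N", [(2, 2, 2), (4, 3, 4), (6, 4, 6), (3, 3, 2)])
    def test_zero_derivative_part_is_truncated_bell_series(self, n, order, N):
        exp = expand_with_derivatives(n, order, N)
        got = {}
        for t in exp.derivative_free:
            counts = {}
            for p, _ in t.factors:
                counts[p] = counts.get(p, 0) + 1
            key = (t.tau_power, tuple(sorted(counts.items())))
            got[key] = got.get(key, Fraction(0)) + t.coefficient
        full = moments_from_km(n)
        want = {
            (t.tau_power, t.exponents): t.coefficient
            for t in full.terms
            if t.tau_power <= order and max(p for p, _ in t.exponents) <= N
        }
        assert {k: v for k, v in got.items() if v != 0} == want

    def test_third_order_fokker_planck_m1(self):
        exp = expand_with_derivatives(1, 3, 2)
        got = {
            t.factors: t.coefficient * 6
            for t in exp.terms
            if t.tau_power == 3 and any(d > 0 for _, d in t.factors)
        }
        assert got == {k: Fraction(v) for k, v in PHI3_M1_FP.items()}

    def test_third_order_fokker_planck_m2(self):
        exp = expand_with_derivatives(2, 3, 2)
        got = {
            t.factors: t.coefficient * 3
            for t in exp.terms
            if t.tau_power == 3 and any(d > 0 for _, d in t.factors)
        }
        assert got == {k: Fraction(v) for k, v in PHI3_M2_FP.items()}

    def test_max_deriv_cap_flags_truncation(self):
        capped = expand_with_derivatives(1, 3, 2, max_deriv=1)
        assert capped.truncated
        full = expand_with_derivatives(1, 3, 2)
        assert not full.truncated
        assert len(capped.terms) < len(full.terms)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            expand_with_derivatives(0, 2, 2)
        with pytest.raises(ValueError):
            expand_with_derivatives(2, 0, 2)


class TestRendering:
    @pytest.mark.parametrize(
        "builder,expected",
        [
            (lambda: moments_from_km(1), "tau*D1"),
            (lambda: moments_from_km(2), "2*tau*D2 + tau^2*D1^2"),
            (lambda: km_from_moments(1), "M1/tau"),
            (lambda: km_from_moments(2), "(M2 - M1^2)/(2*tau)"),
            (lambda: km_from_moments(3), "(M3 - 3*M1*M2 + 2*M1^3)/(6*tau)"),
        ],
    )
    def test_plain_strings(self, builder, expected):
        assert render(builder()) == expected

    @pytest.mark.parametrize("n", range(1, 7))
    @pytest.mark.parametrize("direction", ["forward", "inverse"])
    def test_render_parse_round_trip(self, n, direction):
        e = moments_from_km(n) if direction == "forward" else km_from_moments(n)
        text = render(e)
        assert render(parse(text)) == text

    def test_latex_smoke(self):
        out = render(moments_from_km(2), format="latex")
        assert "tau" in out and "D" in out
        out2 = render(expand_with_derivatives(1, 2, 2), format="latex")
        assert "D" in out2

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError):
            render(moments_from_km(1), format="markdown")
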