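"""Series engine: compensated sums, coefficient tables, bSFS assembly."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from coalgf import (
    DemographicModel,
    GfEvaluator,
    bsfs_probabilities,
    compensated_sum,
    evaluate_laplace,
    exp_poly_coeffs,
    inverse_poly_coeffs,
    inverted_node_series,
    propagate_series,
    series_product,
)
from coalgf.laplace import FirstDegreePoly, inverse_laplace_product
from coalgf.taylor import negpow_poly_coeffs, node_series


class TestCompensatedSum:
    def test_catastrophic_cancellation_recovered(self):
        assert compensated_sum([1e16, 1.0, -1e16]) == 1.0
        assert sum([1e16, 1.0, -1e16]) == 0.0  # what naive summation loses

    def test_all_zeros(self):
        assert compensated_sum([0.0] * 5) == 0.0

    @given(st.lists(st.floats(-1e12, 1e12, allow_nan=False), max_size=30),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant_and_exact(self, xs, rnd):
        exact = float(sum(Fraction(x) for x in xs))
        got = compensated_sum(xs)
        assert got == pytest.approx(exact, rel=1e-15, abs=1e-300)
        shuffled = list(xs)
        rnd.shuffle(shuffled)
        assert compensated_sum(shuffled) == pytest.approx(
            got, rel=1e-15, abs=1e-300
        )


def _naive_truncated_product(A, B):
    C = np.zeros(A.shape)
    for k in np.ndindex(A.shape):
        total = 0.0
        for j in itertools.product(*(range(x + 1) for x in k)):
            total += A[j] * B[tuple(a - b for a, b in zip(k, j))]
        C[k] = total
    return C


class TestSeriesProduct:
    def test_identity_series_is_neutral(self):
        rng = np.random.default_rng(0)
        B = rng.normal(size=(3, 2, 4))
        A = np.zeros_like(B)
        A[0, 0, 0] = 1.0
        assert np.allclose(series_product(A, B), B)

    def test_univariate_square(self):
        A = np.array([1.0, 1.0, 0.0])
        assert np.allclose(series_product(A, A), [1.0, 2.0, 1.0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            series_product(np.zeros((2, 2)), np.zeros((2, 3)))

    @given(seed=st.integers(0, 999))
    @settings(max_examples=25, deadline=None)
    def test_matches_naive_truncated_convolution(self, seed):
        rng = np.random.default_rng(seed)
        ndim = int(rng.integers(1, 4))
        shape = tuple(int(rng.integers(1, 4)) for _ in range(ndim))
        A, B = rng.normal(size=shape), rng.normal(size=shape)
        assert np.allclose(
            series_product(A, B), _naive_truncated_product(A, B),
            rtol=1e-12, atol=1e-12,
        )


def _sympy_table(expr, syms, point, kmax):
    """Taylor coefficients of expr around point via symbolic differentiation."""
    out = np.zeros(tuple(k + 1 for k in kmax))
    for k in np.ndindex(out.shape):
        d = expr
        for s, ki in zip(syms, k):
            d = sympy.diff(d, s, ki)
        val = d.subs(dict(zip(syms, point)))
        out[k] = float(val) / math.prod(math.factorial(ki) for ki in k)
    return out


class TestCoefficientTables:
    def test_zeroth_coefficient_is_the_value(self):
        f = FirstDegreePoly(2.0, (3, 1))
        w0 = (0.2, 0.5)
        assert inverse_poly_coeffs(f, (2, 2), w0)[0, 0] == pytest.approx(
            1 / f(np.array(w0))
        )
        assert exp_poly_coeffs(-1.3, f, (2, 2), w0)[0, 0] == pytest.approx(
            math.exp(-1.3 * f(np.array(w0)))
        )

    def test_univariate_second_coefficient_closed_form(self):
        # 1/(b + c x): coefficient at k=2 around x0 is c^2 / f(x0)^3
        b, x0 = 1.7, 0.25
        table = inverse_poly_coeffs(FirstDegreePoly(b, (1,)), (3,), (x0,))
        x = sympy.Symbol("x")
        ref = _sympy_table(1 / (b + x), [x], [x0], (3,))
        assert np.allclose(table, ref, rtol=1e-12)
        assert table[2] == pytest.approx(1.0 / (b + x0) ** 3, rel=1e-12)

    @pytest.mark.parametrize("t", [1, 2, 3])
    def test_negative_powers_match_symbolic_differentiation(self, t):
        x, y = sympy.symbols("x y")
        f = FirstDegreePoly(1.3, (2, 3))
        w0 = (0.1, 0.3)
        got = negpow_poly_coeffs(f, t, (2, 2), w0)
        ref = _sympy_table((1.3 + 2 * x + 3 * y) ** (-t), [x, y], w0, (2, 2))
        assert np.allclose(got, ref, rtol=1e-10)

    def test_exponential_table_matches_symbolic_differentiation(self):
        x, y = sympy.symbols("x y")
        f = FirstDegreePoly(0.8, (1, 2))
        c, w0 = -0.9, (0.15, 0.4)
        got = exp_poly_coeffs(c, f, (2, 2), w0)
        ref = _sympy_table(sympy.exp(c * (0.8 + x + 2 * y)), [x, y], w0, (2, 2))
        assert np.allclose(got, ref, rtol=1e-10)

    def test_inverse_table_matches_finite_differences(self):
        f = FirstDegreePoly(2.1, (1, 2))
        w0 = np.array([0.3, 0.2])
        got = inverse_poly_coeffs(f, (2, 2), w0)
        h = 1e-4
        # central finite differences of 1/f for first-order coefficients
        for axis in (0, 1):
            e = np.zeros(2)
            e[axis] = h
            d = (1 / f(w0 + e) - 1 / f(w0 - e)) / (2 * h)
            idx = tuple(1 if a == axis else 0 for a in range(2))
            assert got[idx] == pytest.approx(d, rel=1e-6)

    def test_pole_at_expansion_point_rejected(self):
        with pytest.raises(ZeroDivisionError):
            inverse_poly_coeffs(FirstDegreePoly(-0.5, (1,)), (2,), (0.5,))


class TestInvertedNodeSeries:
    def test_single_pole_reduces_to_the_exponential_table(self):
        p = FirstDegreePoly(1.4, (2,))
        T, w0 = 0.8, (0.3,)
        got = inverted_node_series([p], T, (3,), w0)
        assert np.allclose(got, exp_poly_coeffs(-T, p, (3,), w0), rtol=1e-12)

    def test_omega_independent_poles_give_a_constant_series(self):
        p1 = FirstDegreePoly(1.0, (0,))
        p2 = FirstDegreePoly(2.0, (0,))
        got = inverted_node_series([p1, p2], 1.0, (2,), (0.5,))
        assert got[0] == pytest.approx(math.exp(-1) - math.exp(-2), rel=1e-12)
        assert np.allclose(got[1:], 0.0)

    @pytest.mark.parametrize("poles", [
        [(1.2, (2,)), (2.5, (1,))],
        [(0.9, (3,)), (0.9, (3,))],              # confluent pair
        [(0.0, (0,)), (1.5, (2,)), (2.2, (1,))],  # with the 1/δ zero pole
        [(1.0, (2,)), (1.0 + 5e-12, (2,))],       # near-confluent values
    ])
    def test_series_matches_finite_differences_of_scalar_inverse(self, poles):
        polys = [FirstDegreePoly(b, c) for b, c in poles]
        T, w0 = 0.9, 0.35
        got = inverted_node_series(polys, T, (2,), (w0,))

        def scalar(w):
            return inverse_laplace_product([p((w,)) for p in polys], T)

        h = 1e-4
        f0 = scalar(w0)
        d1 = (scalar(w0 + h) - scalar(w0 - h)) / (2 * h)
        d2 = (scalar(w0 + h) - 2 * f0 + scalar(w0 - h)) / h ** 2
        assert got[0] == pytest.approx(f0, rel=1e-10)
        assert got[1] == pytest.approx(d1, rel=1e-5)
        assert got[2] == pytest.approx(d2 / 2, rel=1e-3)


class TestPropagateSeries:
    def test_single_path_model_is_a_product_of_node_series(self, single_pop2):
        ev = GfEvaluator(single_pop2)
        got = propagate_series(ev.cgraph, (3,), (0.4,))
        expected = node_series(ev.cgraph.nodes[0], None, (3,), (0.4,))
        assert np.allclose(got, expected)

    @pytest.mark.parametrize("which", ["toy", "mig2"])
    def test_root_table_matches_bruteforce_path_products(
        self, which, toy_eval, mig2_eval
    ):
        ev = {"toy": toy_eval, "mig2": mig2_eval}[which]
        K = ev.n_branch_types
        kmax = (2,) * K
        w0 = np.full(K, 0.3)
        T = 0.9 if ev.model.event is not None else None
        got = propagate_series(ev.cgraph, kmax, w0, T=T)
        cg = ev.cgraph
        tables = [node_series(n, T, kmax, w0) for n in cg.nodes]
        total = np.zeros_like(got)
        stack = [(r, tables[r]) for r in cg.roots]
        while stack:
            n, acc = stack.pop()
            if not cg.children[n]:
                total = total + acc
                continue
            for c in cg.children[n]:
                stack.append((c, series_product(acc, tables[c])))
        assert np.allclose(got, total, rtol=1e-9, atol=1e-12)

    def test_zeroth_slot_equals_the_scalar_transform(self, im2_eval):
        K = im2_eval.n_branch_types
        w0 = np.full(K, 0.25)
        table = propagate_series(im2_eval.cgraph, (1,) * K, w0, T=1.3)
        scalar = im2_eval.laplace(w0, 1.3)
        assert table[(0,) * K] == pytest.approx(scalar, rel=1e-10)


class TestBsfsProbabilities:
    def test_pairwise_closed_form(self, single_pop2):
        for theta in (0.4, 1.0, 2.7):
            arr = bsfs_probabilities(single_pop2, theta, (3,))
            for k in range(4):
                assert arr[(k,)] == pytest.approx(
                    theta ** k / (1 + theta) ** (k + 1), abs=1e-12
                )
            assert arr[(4,)] == pytest.approx(
                1 - sum(theta ** k / (1 + theta) ** (k + 1) for k in range(4)),
                abs=1e-12,
            )

    @pytest.mark.parametrize("which", ["toy", "mig2", "im2"])
    def test_normalization_including_residual_bins(
        self, which, toy_eval, mig2_eval, im2_eval
    ):
        ev = {"toy": toy_eval, "mig2": mig2_eval, "im2": im2_eval}[which]
        arr = ev.bsfs(1.152, 2)
        assert arr.total() == pytest.approx(1.0, abs=1e-8)
        assert np.all(arr.values >= 0)
        assert np.all(arr.values <= 1)

    def test_structural_zeros_are_exact(self, mig2_eval):
        arr = mig2_eval.bsfs(0.9, 2)
        mask = arr.layout.mask()
        mask[(0,) * 4] = True
        assert np.all(arr.values[~mask] == 0.0)

    def test_increasing_kmax_extends_without_changing_entries(self, mig2_eval):
        small = mig2_eval.bsfs(0.8, (1, 1, 1, 1))
        big = mig2_eval.bsfs(0.8, (2, 2, 2, 2))
        sub = tuple(slice(0, 2) for _ in range(4))
        assert np.allclose(small.values[sub], big.values[sub], atol=1e-12)

    def test_nonpositive_theta_rejected(self, single_pop2):
        with pytest.raises(ValueError):
            bsfs_probabilities(single_pop2, 0.0, (2,))
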