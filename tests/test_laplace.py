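"""Transform evaluation: edge factors, inversion, propagation, collapse."""

import math

import mpmath
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coalgf import (
    ComputationalGraph,
    DemographicModel,
    GfEvaluator,
    eval_edge,
    evaluate_laplace,
    inverse_laplace_product,
    propagate,
)
from coalgf.laplace import DegenerateRateError
from coalgf.statespace import EdgeEquation


def _invert_oracle(poles, T):
    """High-precision numerical inverse Laplace of Π 1/(c_i + s)."""
    if T == 0:
        # numerical inversion is singular at 0; use a series fallback
        T = 1e-30
    with mpmath.workdps(60):
        f = lambda s: mpmath.fprod([1 / (c + s) for c in poles])
        return float(mpmath.invertlaplace(f, T, method="talbot"))


class TestEvalEdge:
    def test_certain_event_has_probability_one(self):
        eq = EdgeEquation(p=(1, 0), q=(1, 2))
        assert eval_edge(eq, np.array([1.0, 0.0])) == 1.0

    def test_marked_interval_probability(self):
        eq = EdgeEquation(p=(1, 0), q=(1, 2))
        assert eval_edge(eq, np.array([1.0, 0.5])) == pytest.approx(0.5)

    def test_degenerate_rate_raises(self):
        eq = EdgeEquation(p=(1, 0), q=(1, 2))
        with pytest.raises(DegenerateRateError):
            eval_edge(eq, np.array([0.0, 0.0]))


class TestInverseLaplaceProduct:
    def test_single_pole_is_an_exponential(self):
        assert inverse_laplace_product([0.8], 1.3) == pytest.approx(
            math.exp(-0.8 * 1.3), rel=1e-12
        )

    def test_two_distinct_poles(self):
        got = inverse_laplace_product([1.0, 2.0], 1.0)
        assert got == pytest.approx(math.exp(-1) - math.exp(-2), rel=1e-12)
        assert got == pytest.approx(0.232544, abs=1e-6)

    def test_repeated_pole_uses_confluent_formula(self):
        assert inverse_laplace_product([1.0, 1.0], 1.0) == pytest.approx(
            math.exp(-1.0), rel=1e-12
        )
        # triple pole: T^2/2 e^{-cT}
        assert inverse_laplace_product([2.0] * 3, 0.9) == pytest.approx(
            0.9 ** 2 / 2 * math.exp(-2 * 0.9), rel=1e-12
        )

    def test_empty_product_is_the_dirac_case(self):
        assert inverse_laplace_product([], 1.0) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            inverse_laplace_product([1.0], -0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_high_precision_numerical_inversion(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(1, 6)
        poles = rng.uniform(0.1, 6.0, k).tolist()
        if seed % 2:  # near-confluent pair
            poles.append(poles[0] + rng.uniform(0, 1) * 1e-11)
        T = float(rng.uniform(0.05, 3.0))
        got = inverse_laplace_product(poles, T)
        ref = _invert_oracle(poles, T)
        assert got == pytest.approx(ref, rel=1e-9)

    def test_zero_pole_integrates_the_density(self):
        # 1/s · Π 1/(c+s) is the time-integral of the density up to T
        with mpmath.workdps(50):
            ref = float(mpmath.quad(
                lambda t: mpmath.exp(-t) - mpmath.exp(-2 * t), [0, 1.5]
            ))
        assert inverse_laplace_product([0.0, 1.0, 2.0], 1.5) == pytest.approx(
            ref, rel=1e-9
        )


def _brute_force_paths(children, roots):
    out = []
    stack = [(r, (r,)) for r in roots]
    while stack:
        n, path = stack.pop()
        if not children[n]:
            out.append(path)
            continue
        for c in children[n]:
            stack.append((c, path + (c,)))
    return out


class TestPropagate:
    def test_chain_graph_is_a_plain_product(self):
        children = [[1], [2], []]
        got = propagate(children, [2.0, 3.0, 5.0], roots=[0], topo=[2, 1, 0])
        assert got == 30.0

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_random_dags_match_exhaustive_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        children = [[] for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.35:
                    children[i].append(j)
        values = rng.uniform(-2, 2, n).tolist()
        roots = [i for i in range(n) if not any(i in c for c in children)]
        topo = list(reversed(range(n)))
        got = propagate(children, values, roots, topo)
        expected = sum(
            math.prod(values[i] for i in p)
            for p in _brute_force_paths(children, roots)
        )
        assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_graph_value_equals_sum_over_path_products(self, toy_eval, mig2_eval):
        for ev, omega, T in [
            (toy_eval, [0.3, 0.1], 0.7),
            (mig2_eval, [0.2, 0.4, 0.1, 0.3], None),
        ]:
            g = ev.graph
            from coalgf.laplace import rate_vector

            got = evaluate_laplace(ev.cgraph, omega, T)
            # brute force over state-graph paths, inverting each path's
            # δ prefix directly
            total = 0.0
            for path in g.paths():
                term = 1.0
                poles = []
                saw_delta = False
                for ei in path:
                    eq = g.equations[g.edges[ei].eq]
                    lay = g.layout
                    r = rate_vector(g, np.asarray(omega), delta=0.0)
                    num = float(np.dot(eq.p, r))
                    den = float(np.dot(eq.q, r))
                    if lay.has_delta and eq.q[lay.delta_slot] > 0:
                        poles.append(den)
                        if eq.p[lay.delta_slot] > 0:
                            saw_delta = True
                            num = 1.0
                        term *= num
                    else:
                        term *= num / den
                if g.layout.has_delta:
                    if not saw_delta:
                        poles.append(0.0)
                    term *= inverse_laplace_product(poles, T)
                total += term
            assert got == pytest.approx(total, rel=1e-10)


class TestCollapse:
    def test_toy_model_collapse_shape(self, toy_eval):
        cg = toy_eval.cgraph
        kinds = sorted(n.kind for n in cg.nodes)
        assert kinds.count("collapsed") == 2
        assert kinds.count("plain") == 4
        # collapsed prefixes have 2 and 1 edges (coalescence+event, event)
        sizes = sorted(len(n.edges) for n in cg.nodes if n.kind == "collapsed")
        assert sizes == [1, 2]
        # the two-pole prefix and one continuation node are shared
        shared = [c for ch in cg.children for c in ch]
        assert len(shared) > len(set(shared))

    def test_migration_only_collapse_is_the_edge_dual(self, mig2_eval):
        cg = mig2_eval.cgraph
        assert cg.n_nodes == mig2_eval.graph.n_edges
        assert all(n.kind == "plain" for n in cg.nodes)


class TestEvaluateLaplace:
    def test_total_probability_at_omega_zero(self, toy_eval, im2_eval, mig2_eval):
        for ev, T in [(toy_eval, 0.0), (toy_eval, 1.7), (im2_eval, 0.4),
                      (im2_eval, None), (mig2_eval, None)]:
            K = ev.n_branch_types
            assert ev.laplace(np.zeros(K), T) == pytest.approx(1.0, abs=1e-12)

    def test_pairwise_coalescent_closed_form(self, single_pop2):
        # E[e^{-ω·2T2}] with T2 ~ Exp(1): 1/(1+2ω)
        for w in (0.0, 0.4, 1.0, 3.3):
            assert evaluate_laplace(single_pop2, [w]) == pytest.approx(
                1 / (1 + 2 * w), rel=1e-12
            )

    def test_expected_total_length_by_finite_differences(self, single_pop2):
        h = 1e-6
        d = (evaluate_laplace(single_pop2, [h]) -
             evaluate_laplace(single_pop2, [-h])) / (2 * h)
        assert -d == pytest.approx(2.0, rel=1e-6)

    def test_completely_monotone_in_each_omega(self, im2_eval):
        K = im2_eval.n_branch_types
        for axis in range(K):
            vals = []
            for w in np.linspace(0, 2, 9):
                omega = np.full(K, 0.15)
                omega[axis] = w
                vals.append(im2_eval.laplace(omega, 1.3))
            assert all(0 < v <= 1 for v in vals)
            assert all(a > b for a, b in zip(vals, vals[1:]))
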