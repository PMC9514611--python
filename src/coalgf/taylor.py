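"""Truncated multivariate Taylor propagation of the transform.

The probability of observing ``k_i`` mutations on each branch type within a
block is a Poisson mixture over branch lengths and equals, up to the factor
``(-θ/2)^{Σk}``, a Taylor coefficient of the Laplace transform expanded at
``ω = θ/2``.  Instead of symbolic differentiation, every node of the
computational graph gets the coefficient table of its own factor in closed
form, and tables are propagated with the graph sweep: addition of tables is
elementwise, multiplication is truncated multi-index convolution.

Coefficients (derivatives divided by ``Πk_i!``) rather than raw derivatives
are stored throughout, which keeps magnitudes down by ``(Σk)!`` and limits
rounding error; every reduction uses compensated (error-free transformation)
summation since the summands alternate in sign.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Sequence, Union

import numpy as np

from .laplace import (
    POLE_TOL,
    ComputationalGraph,
    CompNode,
    FirstDegreePoly,
    propagate,
)
from .model import BranchTypeSet, DemographicModel
from .mutations import ConfigArray, array_layout, normalize_kmax
from .statespace import StateGraph, build_state_graph

# ---------------------------------------------------------------------------
# Compensated summation (error-free transformations)
# ---------------------------------------------------------------------------


def compensated_sum(values: Sequence[float]) -> float:
    """Sum with a running error term (Neumaier's variant of two-sum).

    Accurate to a couple of ulp even under heavy cancellation, e.g.
    ``[1e16, 1.0, -1e16] -> 1.0`` where naive left-to-right gives 0.
    """
    s = 0.0
    err = 0.0
    for x in values:
        x = float(x)
        t = s + x
        if abs(s) >= abs(x):
            err += (s - t) + x
        else:
            err += (x - t) + s
        s = t
    return s + err


class _ArrayAccumulator:
    """Elementwise compensated accumulation of equal-shape arrays."""

    def __init__(self, shape: tuple[int, ...]) -> None:
        self.s = np.zeros(shape)
        self.err = np.zeros(shape)

    def add(self, x: np.ndarray) -> None:
        t = self.s + x
        big = np.abs(self.s) >= np.abs(x)
        self.err += np.where(big, (self.s - t) + x, (x - t) + self.s)
        self.s = t

    def total(self) -> np.ndarray:
        return self.s + self.err


# ---------------------------------------------------------------------------
# Series tables
# ---------------------------------------------------------------------------
#
# A series table is a dense ndarray with one axis per branch type and sizes
# kmax_i + 1; entry [k] is the Taylor coefficient at multi-index k around
# the expansion point ω0.


def identity_series(kmax: tuple[int, ...]) -> np.ndarray:
    out = np.zeros(tuple(k + 1 for k in kmax))
    out[(0,) * len(kmax)] = 1.0
    return out


def series_product(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Truncated product ``C[k] = Σ_{j≤k} A[j]·B[k-j]`` (compensated)."""
    if A.shape != B.shape:
        raise ValueError("series tables must share a shape")
    acc = _ArrayAccumulator(A.shape)
    for j in np.ndindex(A.shape):
        aj = A[j]
        if aj == 0.0:
            continue
        dest = tuple(slice(jj, None) for jj in j)
        src = tuple(slice(0, s - jj) for jj, s in zip(j, A.shape))
        contrib = np.zeros(A.shape)
        contrib[dest] = aj * B[src]
        acc.add(contrib)
    return acc.total()


def _multi_factorial(shape: tuple[int, ...]) -> np.ndarray:
    """``Π k_i!`` over the table."""
    out = np.ones(shape)
    for ax, n in enumerate(shape):
        f = np.array([math.factorial(i) for i in range(n)])
        sh = [1] * len(shape)
        sh[ax] = n
        out = out * f.reshape(sh)
    return out


def _order_table(shape: tuple[int, ...]) -> np.ndarray:
    """``s = Σ k_i`` over the table."""
    out = np.zeros(shape)
    for ax, n in enumerate(shape):
        v = np.arange(n, dtype=float)
        sh = [1] * len(shape)
        sh[ax] = n
        out = out + v.reshape(sh)
    return out


def _coeff_powers(coeffs: Sequence[float], shape: tuple[int, ...]) -> np.ndarray:
    """``Π c_i^{k_i}`` over the table."""
    out = np.ones(shape)
    for ax, (c, n) in enumerate(zip(coeffs, shape)):
        v = np.array([c ** i for i in range(n)])
        sh = [1] * len(shape)
        sh[ax] = n
        out = out * v.reshape(sh)
    return out


def negpow_poly_coeffs(f: FirstDegreePoly, t: int, kmax, omega0) -> np.ndarray:
    """Taylor table of ``f(ω)^{-t}`` around ``ω0`` for first-degree ``f``.

    The coefficient at multi-index ``k`` (with ``s = Σk_i``) is::

        (-1)^s (s+t-1)! / ((t-1)! Π k_i!) · Π c_i^{k_i} / f(ω0)^{s+t}

    ``t = 1`` is the non-inverted equation case ``1/f``.
    """
    kmax = tuple(kmax)
    shape = tuple(k + 1 for k in kmax)
    f0 = f(np.asarray(omega0, dtype=float))
    if f0 == 0.0:
        raise ZeroDivisionError("pole at the expansion point: f(ω0) = 0")
    s = _order_table(shape)
    rising = np.vectorize(
        lambda si: math.factorial(int(si) + t - 1) / math.factorial(t - 1)
    )(s)
    table = (
        (-1.0) ** s
        * rising
        / _multi_factorial(shape)
        * _coeff_powers(f.coeffs, shape)
        * f0 ** (-(s + t))
    )
    return table


def inverse_poly_coeffs(f: FirstDegreePoly, kmax, omega0) -> np.ndarray:
    """Taylor table of ``1/f(ω)``; see :func:`negpow_poly_coeffs`."""
    return negpow_poly_coeffs(f, 1, kmax, omega0)


def exp_poly_coeffs(c: float, f: FirstDegreePoly, kmax, omega0) -> np.ndarray:
    """Taylor table of ``e^{c·f(ω)}`` around ``ω0``: coefficient at ``k`` is
    ``c^s Π c_i^{k_i} e^{c f(ω0)} / Π k_i!``."""
    kmax = tuple(kmax)
    shape = tuple(k + 1 for k in kmax)
    f0 = f(np.asarray(omega0, dtype=float))
    s = _order_table(shape)
    return (
        c ** s
        * _coeff_powers(f.coeffs, shape)
        * math.exp(c * f0)
        / _multi_factorial(shape)
    )


# ---------------------------------------------------------------------------
# Series of an inverted (collapsed) node
# ---------------------------------------------------------------------------


def inverted_node_series(poles: Sequence[FirstDegreePoly], T: float,
                         kmax, omega0, *, _depth: int = 0) -> np.ndarray:
    """Series table of ``L^-1[Π_i 1/(c_i(ω)+δ)](T)`` in the ω variables.

    Identical pole polynomials are grouped and handled with the confluent
    (higher-order-pole) residue formula, realized as a short expansion in
    the auxiliary variable ``u = δ + c``.  Distinct polynomials whose values
    collide at ``ω0`` (a removable singularity of the partial-fraction form)
    are split by a symmetric ±ε perturbation whose average cancels the
    leading error term.
    """
    kmax = tuple(kmax)
    omega0 = np.asarray(omega0, dtype=float)
    shape = tuple(k + 1 for k in kmax)
    if T < 0:
        raise ValueError("T must be non-negative")
    if len(poles) == 0:
        return identity_series(kmax)

    groups: list[tuple[FirstDegreePoly, int]] = []
    for p in poles:
        for gi, (gp, m) in enumerate(groups):
            if gp == p:
                groups[gi] = (gp, m + 1)
                break
        else:
            groups.append((p, 1))

    # value collisions between distinct polynomials -> perturb symmetrically
    vals = [gp(omega0) for gp, _ in groups]
    collide = any(
        abs(vals[i] - vals[j]) < POLE_TOL * max(1.0, abs(vals[i]))
        for i in range(len(vals))
        for j in range(i + 1, len(vals))
    )
    if collide:
        if _depth > 0:
            raise FloatingPointError("unresolvable pole collision")
        scale = max(1.0, max(abs(v) for v in vals))
        eps = 1e-6 * scale
        shifts = {}
        seen: dict[float, int] = {}
        for gi, v in enumerate(vals):
            key = round(v / (POLE_TOL * scale))
            rank = seen.get(key, 0)
            seen[key] = rank + 1
            shifts[gi] = rank * eps
        def shifted(sign: float) -> list[FirstDegreePoly]:
            out = []
            for gi, (gp, m) in enumerate(groups):
                out.extend([FirstDegreePoly(gp.b + sign * shifts[gi], gp.coeffs)] * m)
            return out
        up = inverted_node_series(shifted(+1.0), T, kmax, omega0, _depth=1)
        dn = inverted_node_series(shifted(-1.0), T, kmax, omega0, _depth=1)
        return 0.5 * (up + dn)

    acc = _ArrayAccumulator(shape)
    for gi, (gp, m) in enumerate(groups):
        # u-series (length m) with series-table coefficients of
        # Π_{g'≠g} (c_g'(ω) - c_g(ω) + u)^{-m_g'} · e^{uT}
        useries: list[Optional[np.ndarray]] = [None] * m
        useries[0] = identity_series(kmax)
        for gj, (op, mo) in enumerate(groups):
            if gj == gi:
                continue
            d = op - gp
            fac = [
                _binom_neg_coeff(mo, j) * negpow_poly_coeffs(d, mo + j, kmax, omega0)
                for j in range(m)
            ]
            useries = _useries_mul(useries, fac, kmax)
        expo = [
            (T ** j / math.factorial(j)) * identity_series(kmax)
            for j in range(m)
        ]
        useries = _useries_mul(useries, expo, kmax)
        term = series_product(
            useries[m - 1], exp_poly_coeffs(-T, gp, kmax, omega0)
        )
        acc.add(term)
    return acc.total()


def _binom_neg_coeff(m: int, j: int) -> float:
    return (-1.0) ** j * math.comb(m + j - 1, j)


def _useries_mul(a: list, b: list, kmax) -> list:
    n = len(a)
    out: list[Optional[np.ndarray]] = [None] * n
    for i, ai in enumerate(a):
        if ai is None:
            continue
        for j in range(min(len(b), n - i)):
            contrib = series_product(ai, b[j])
            out[i + j] = contrib if out[i + j] is None else out[i + j] + contrib
    zero = np.zeros(tuple(k + 1 for k in kmax))
    return [zero if x is None else x for x in out]


# ---------------------------------------------------------------------------
# Node series and propagation
# ---------------------------------------------------------------------------


def node_series(node: CompNode, T: Optional[float], kmax, omega0) -> np.ndarray:
    """Taylor table of one computational-graph node's factor."""
    if node.kind == "plain":
        return node.num * inverse_poly_coeffs(node.poly, kmax, omega0)
    if T is None:
        raise ValueError("model has a discrete event: T is required")
    table = node.num * inverted_node_series(node.poles, T, kmax, omega0)
    for f in node.factors:
        table = series_product(table, inverse_poly_coeffs(f, kmax, omega0))
    return table


def propagate_series(cg: ComputationalGraph, kmax, omega0,
                     T: Optional[float] = None) -> np.ndarray:
    """Root Taylor table of the whole transform (sum over paths of
    truncated products), via the generic graph sweep."""
    kmax = normalize_kmax(kmax, cg.graph.layout.n_types)
    model = cg.graph.model
    if model.event is not None and T is None:
        T = model.event.time
    values = [node_series(n, T, kmax, omega0) for n in cg.nodes]
    return propagate(
        cg.children, values, cg.roots, cg.topological_order(),
        add=np.add, mul=series_product,
    )


# ---------------------------------------------------------------------------
# bSFS assembly
# ---------------------------------------------------------------------------


def _scale_table(theta: float, shape: tuple[int, ...]) -> np.ndarray:
    """``(-θ/2)^{Σ k_i}`` over a coefficient table."""
    return (-theta / 2.0) ** _order_table(shape)


def bsfs_probabilities(source: Union[DemographicModel, StateGraph, ComputationalGraph],
                       theta: float, kmax, T: Optional[float] = None, *,
                       phased: bool = False, rooted: bool = False) -> ConfigArray:
    """Exact probabilities of all block-wise mutation configurations.

    ``P(k) = (-θ/2)^{Σk} · c_k`` with ``c_k`` the root Taylor coefficient
    at expansion point ``ω0 = θ/2`` per branch type (the zero-mark
    probability of a Poisson marking process with intensity ``θ/2`` per
    unit branch length).  Residual bins (``k_i > kmax_i`` jointly for a set
    ``S`` of types) are filled by inclusion–exclusion over marginal tables
    recomputed with ``ω_i = 0`` for ``i ∈ S`` (unmarking those types).

    The array sums to one; structurally impossible cells are exact zeros.
    """
    if not theta > 0:
        raise ValueError("theta must be strictly positive")
    if isinstance(source, DemographicModel):
        bts = BranchTypeSet(source, phased=phased, rooted=rooted)
        cg = ComputationalGraph(build_state_graph(source, bts))
    elif isinstance(source, StateGraph):
        cg = ComputationalGraph(source)
    else:
        cg = source
    graph = cg.graph
    bts = graph.bts
    K = len(bts)
    kmax = normalize_kmax(kmax, K)
    model = graph.model
    if model.event is not None and T is None:
        T = model.event.time

    layout = array_layout(kmax, graph)
    shape_full = layout.shape

    # marginal coefficient tables: key = frozenset of unmarked types
    tables: dict[frozenset, np.ndarray] = {}

    def marginal(W: frozenset) -> np.ndarray:
        """P(exact counts on types not in W; any counts on W), k <= kmax."""
        if W not in tables:
            km = tuple(0 if i in W else kmax[i] for i in range(K))
            w0 = np.array([0.0 if i in W else theta / 2.0 for i in range(K)])
            coeff = propagate_series(cg, km, w0, T=T)
            tables[W] = coeff * _scale_table(theta, coeff.shape)
        return tables[W]

    base = marginal(frozenset())
    values = np.zeros(shape_full)
    sub = tuple(slice(0, k + 1) for k in kmax)
    values[sub] = base

    # residual bins, inclusion-exclusion over which residual types are
    # instead bounded by kmax
    residual_sets = sorted(
        {frozenset(i for i in range(K) if s >> i & 1) for s in layout.supports},
        key=lambda fs: (len(fs), sorted(fs)),
    )
    for S in residual_sets:
        if not S:
            continue
        acc_shape = tuple(
            1 if i in S else kmax[i] + 1 for i in range(K)
        )
        acc = np.zeros(acc_shape)
        for r in range(len(S) + 1):
            for R in itertools.combinations(sorted(S), r):
                Rs = frozenset(R)
                M = marginal(S - Rs)
                # sum over the bounded residual axes (0..kmax)
                term = M.sum(axis=tuple(sorted(Rs)), keepdims=True)
                acc = acc + (-1.0) ** r * term
        dest = tuple(
            kmax[i] + 1 if i in S else slice(0, kmax[i] + 1)
            for i in range(K)
        )
        values[dest] = acc.squeeze(axis=tuple(sorted(S)))

    # structural zeros are exact; tiny negatives from cancellation clipped
    if layout.n_slots <= 10_000_000:
        mask = layout.mask()
        mask[(0,) * K] = True
        values[~mask] = 0.0
    values[(values < 0) & (values > -1e-12)] = 0.0

    return ConfigArray(
        values=values, kmax=kmax, bts=bts, layout=layout,
        meta={"theta": theta, "T": T, "mode": "exact"},
    )
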