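"""Evaluation of the Laplace transform from the state-space graph.

The transform of the joint branch-length distribution is a sum over
root-to-absorption paths of products of per-edge factors ``(p·r)/(q·r)``.
Turning the state graph into a *computational graph* (one node per edge,
children = possible continuations) lets the sum-of-products be evaluated by
a single bottom-up propagation instead of path enumeration.

A discrete event (mass migration at fixed time ``T``) is first modelled as a
competing exponential process with dummy rate ``δ`` and then recovered by an
inverse Laplace transform in ``δ``.  Because every factor carrying ``δ`` has
the form ``1/(c_i + δ)``, the inversion has a closed form via partial
fractions (residue calculus):

    L^-1[ Π_i 1/(c_i + δ) ](T) = Σ_i e^{-c_i T} Π_{j≠i} 1/(c_j - c_i)

with the confluent (higher-order pole) formula for repeated ``c``.  Each
path's ``δ``-dependent prefix is collapsed into a single node holding that
inverse; paths on which the event never fires keep the global ``1/δ`` as an
extra pole at ``c = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .model import BranchTypeSet, DemographicModel, UnsupportedModelError
from .statespace import StateGraph, build_state_graph

#: Relative tolerance below which two poles are treated as confluent.
POLE_TOL = 1e-9


class DegenerateRateError(ZeroDivisionError):
    """Raised when an edge's total outflow rate ``q·r`` vanishes."""


# ---------------------------------------------------------------------------
# Rate vectors and scalar edge evaluation
# ---------------------------------------------------------------------------


def rate_vector(graph: StateGraph, omega: Sequence[float],
                delta: float = 0.0) -> np.ndarray:
    """Assemble the numeric global rate vector ``r = (λ, δ, ω)``.

    λ entries come from the model (coalescence ``Ne_ref/Ne_d`` per deme,
    then per-route migration rates), in the fixed slot order of the graph's
    :class:`~coalgf.statespace.RateLayout`.
    """
    model = graph.model
    lay = graph.layout
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (lay.n_types,):
        raise ValueError(
            f"omega must have one entry per branch type ({lay.n_types})"
        )
    r = np.empty(lay.size)
    for i, d in enumerate(lay.demes):
        r[i] = model.coalescence_rate(d)
    for j, route in enumerate(lay.routes):
        rate = next(
            m.rate for m in model.migrations
            if (m.source, m.dest) == route
        )
        r[len(lay.demes) + j] = rate
    if lay.has_delta:
        r[lay.delta_slot] = delta
    r[lay.omega_offset:] = omega
    return r


def eval_edge(eq, r: np.ndarray) -> float:
    """Evaluate a single edge transform ``(p·r)/(q·r)`` at rate point ``r``."""
    p = np.asarray(eq.p, dtype=float)
    q = np.asarray(eq.q, dtype=float)
    denom = float(q @ r)
    if denom == 0.0:
        raise DegenerateRateError("q·r = 0: no competing process has positive rate")
    return float(p @ r) / denom


# ---------------------------------------------------------------------------
# Closed-form inverse Laplace of a product of simple factors
# ---------------------------------------------------------------------------


def _cluster_poles(c: Sequence[float]) -> list[tuple[float, int]]:
    """Group poles that are equal to within :data:`POLE_TOL` (relative)."""
    cs = sorted(float(x) for x in c)
    groups: list[list[float]] = []
    for x in cs:
        if groups and abs(x - groups[-1][-1]) < POLE_TOL * max(1.0, abs(x)):
            groups[-1].append(x)
        else:
            groups.append([x])
    return [(math.fsum(g) / len(g), len(g)) for g in groups]


def inverse_laplace_product(c: Sequence[float], T: float) -> float:
    """``L^-1[ Π_i 1/(c_i + δ) ]`` evaluated at ``T``.

    ``c`` holds the non-δ parts of the collapsed factors.  Distinct poles
    use the partial-fraction sum of exponentials; (near-)repeated poles
    switch to the confluent formula, computed as the residue via a short
    univariate Taylor expansion around the pole.  An empty ``c`` is the
    Dirac case (the event happening at exactly ``T``) and returns 1.
    """
    if T < 0:
        raise ValueError("T must be non-negative")
    if len(c) == 0:
        return 1.0
    groups = _cluster_poles(c)
    terms = []
    for gi, (cg, m) in enumerate(groups):
        # residue of e^{δT} Π (c+δ)^-mult at δ = -cg:
        # coefficient of u^{m-1} in e^{uT} Π_{g'≠g} (d_g' + u)^{-m_g'},
        # times e^{-cg T}, with d_g' = c_g' - cg.
        series = [0.0] * m
        series[0] = 1.0
        for gj, (co, mo) in enumerate(groups):
            if gj == gi:
                continue
            d = co - cg
            fac = [_binom_neg(mo, j) * d ** (-(mo + j)) for j in range(m)]
            series = _series_mul(series, fac, m)
        expo = [T ** j / math.factorial(j) for j in range(m)]
        series = _series_mul(series, expo, m)
        terms.append(math.exp(-cg * T) * series[m - 1])
    return math.fsum(terms)


def _binom_neg(m: int, j: int) -> float:
    """Coefficient of ``u^j`` in ``(d + u)^{-m}``, without the ``d`` power:
    ``(-1)^j C(m+j-1, j)``."""
    return (-1.0) ** j * math.comb(m + j - 1, j)


def _series_mul(a: list[float], b: list[float], n: int) -> list[float]:
    out = [0.0] * n
    for i, ai in enumerate(a):
        if ai == 0.0:
            continue
        for j in range(min(len(b), n - i)):
            out[i + j] += ai * b[j]
    return out


# ---------------------------------------------------------------------------
# Computational graph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FirstDegreePoly:
    """``f(ω) = b + Σ_k coeffs[k] ω_k`` — the ω-dependence of a factor."""

    b: float
    coeffs: tuple[int, ...]

    def __call__(self, omega: Sequence[float]) -> float:
        return self.b + float(np.dot(self.coeffs, omega))

    def __sub__(self, other: "FirstDegreePoly") -> "FirstDegreePoly":
        return FirstDegreePoly(
            self.b - other.b,
            tuple(a - b for a, b in zip(self.coeffs, other.coeffs)),
        )

    @property
    def is_constant(self) -> bool:
        return not any(self.coeffs)


@dataclass(frozen=True)
class CompNode:
    """One multiplicative factor of the collapsed sum-of-products.

    ``plain`` nodes wrap a single δ-free edge: value ``num / f(ω)``.
    ``collapsed`` nodes wrap a whole δ-involved path prefix: value
    ``num · Π_j num_j/f_j(ω) · L^-1[Π_i 1/(c_i(ω)+δ)](T)``, where the poles
    ``c_i`` come from the prefix edges whose equations contain δ and the
    plain factors ``f_j`` from δ-free edges interleaved in the prefix.  A
    prefix that never realizes the event carries an extra pole at 0 (the
    global ``1/δ``).
    """

    kind: str                       # "plain" | "collapsed"
    num: float
    poly: Optional[FirstDegreePoly] = None        # plain
    poles: tuple[FirstDegreePoly, ...] = ()       # collapsed
    factors: tuple[FirstDegreePoly, ...] = ()     # collapsed, δ-free prefix part
    edges: tuple[int, ...] = ()     # underlying state-graph edge(s)


class ComputationalGraph:
    """Edge-dual graph used for propagation (root = sampling state side)."""

    def __init__(self, graph: StateGraph) -> None:
        self.graph = graph
        self.nodes: list[CompNode] = []
        self.children: list[list[int]] = []
        self.roots: list[int] = []
        self._build()

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    # -- construction -------------------------------------------------------

    def _edge_parts(self, edge_idx: int) -> tuple[float, FirstDegreePoly, bool, bool]:
        """Numerator, denominator ω-poly, has-δ-in-q, is-δ-edge for an edge."""
        g = self.graph
        lay = g.layout
        e = g.edges[edge_idx]
        eq = g.equations[e.eq]
        lam = rate_vector(g, np.zeros(lay.n_types), delta=0.0)
        off = lay.omega_offset
        b = float(np.dot(eq.q[:off], lam[:off]))
        coeffs = eq.q[off:]
        ds = lay.delta_slot
        is_delta_edge = ds is not None and eq.p[ds] > 0
        has_delta = ds is not None and eq.q[ds] > 0
        if is_delta_edge:
            num = 1.0  # the δ numerator cancels against the global 1/δ
        else:
            num = float(np.dot(eq.p[:off], lam[:off]))
        return num, FirstDegreePoly(b, tuple(int(x) for x in coeffs)), has_delta, is_delta_edge

    def _build(self) -> None:
        g = self.graph
        involved = [g.edge_has_delta(ei) for ei in range(g.n_edges)]
        # region states: any outgoing δ-involved edge
        region = [
            any(involved[ei] for ei in g.out_edges[s])
            for s in range(g.n_states)
        ]
        # validate: within a region state, *all* outgoing edges are δ-involved
        for s in range(g.n_states):
            if region[s] and not all(involved[ei] for ei in g.out_edges[s]):
                raise UnsupportedModelError(
                    "state mixes δ-competing and δ-free transitions; "
                    "re-entrant discrete-event regions are unsupported"
                )
        # validate: no descendant of a non-region state is a region state
        order = g.topological_states()
        tainted = [False] * g.n_states  # reachable through a non-region state
        for s in order:
            if tainted[s] and region[s]:
                raise UnsupportedModelError(
                    "discrete event can re-arm after becoming a no-op; "
                    "unsupported model shape"
                )
            for ei in g.out_edges[s]:
                if not region[s]:
                    tainted[g.edges[ei].child] = True
                elif tainted[s]:
                    tainted[g.edges[ei].child] = True

        # plain nodes for every edge leaving a non-region state
        plain_of_edge: dict[int, int] = {}
        for ei, e in enumerate(g.edges):
            if not region[e.parent]:
                num, poly, _, _ = self._edge_parts(ei)
                plain_of_edge[ei] = len(self.nodes)
                self.nodes.append(CompNode(
                    kind="plain", num=num, poly=poly, edges=(ei,),
                ))
                self.children.append([])
        for ei, ni in plain_of_edge.items():
            child_state = g.edges[ei].child
            self.children[ni] = [
                plain_of_edge[e2] for e2 in g.out_edges[child_state]
            ]

        if not any(involved):
            self.roots = [plain_of_edge[ei] for ei in g.out_edges[0]]
            return

        # collapsed nodes: one per path prefix through the δ-region
        stack: list[tuple[int, tuple[int, ...]]] = [(0, ())]
        while stack:
            s, prefix = stack.pop()
            if region[s]:
                for ei in g.out_edges[s]:
                    stack.append((g.edges[ei].child, prefix + (ei,)))
                continue
            # region exited (absorbing, fired, or permanent no-op state)
            num = 1.0
            poles: list[FirstDegreePoly] = []
            factors: list[FirstDegreePoly] = []
            fired = False
            for ei in prefix:
                n_i, poly, has_delta, is_delta = self._edge_parts(ei)
                num *= n_i
                if is_delta:
                    fired = True
                    poles.append(poly)
                elif has_delta:
                    poles.append(poly)
                else:
                    factors.append(poly)
            if not fired:
                poles.append(FirstDegreePoly(0.0, (0,) * g.layout.n_types))
            ni = len(self.nodes)
            self.nodes.append(CompNode(
                kind="collapsed", num=num, poles=tuple(poles),
                factors=tuple(factors), edges=prefix,
            ))
            self.children.append(
                [plain_of_edge[e2] for e2 in g.out_edges[s]]
            )
            self.roots.append(ni)

    # -- traversal ----------------------------------------------------------

    def topological_order(self) -> list[int]:
        """Nodes ordered children-first (reverse BFS from the absorbing side,
        ties broken by node index)."""
        import heapq

        # Kahn from the root side gives parents-first; reversed at the end.
        pending = [0] * self.n_nodes
        for ch in self.children:
            for c in ch:
                pending[c] += 1
        order: list[int] = []
        heap = [i for i, d in enumerate(pending) if d == 0]
        heapq.heapify(heap)
        while heap:
            n = heapq.heappop(heap)
            order.append(n)
            for c in self.children[n]:
                pending[c] -= 1
                if pending[c] == 0:
                    heapq.heappush(heap, c)
        if len(order) != self.n_nodes:
            raise UnsupportedModelError("computational graph contains a cycle")
        order.reverse()
        return order


def collapse_graph(graph: StateGraph) -> ComputationalGraph:
    """Build the computational graph (edge-dual; δ-prefixes collapsed)."""
    return ComputationalGraph(graph)


# ---------------------------------------------------------------------------
# Generic propagation (Alg. "propagate values through graph")
# ---------------------------------------------------------------------------


def propagate(children: Sequence[Sequence[int]], values: Sequence,
              roots: Sequence[int], topo: Sequence[int],
              add: Callable = None, mul: Callable = None):
    """Sum over all paths of products of node values, by one graph sweep.

    ``children[i]`` lists continuation nodes of node ``i``; ``topo`` orders
    children before parents; ``add``/``mul`` default to scalar ``+``/``*``
    but may implement any commutative pair with ``mul`` distributing over
    ``add`` (e.g. truncated Taylor tables).  Children are summed before the
    single multiplication with the parent's own value.
    """
    if add is None:
        add = lambda a, b: a + b
    if mul is None:
        mul = lambda a, b: a * b
    n = len(values)
    acc: list = [None] * n
    for i in topo:
        if values[i] is None:
            raise ValueError(f"missing value for node {i}")
        kids = children[i]
        if not kids:
            acc[i] = values[i]
            continue
        temp = acc[kids[0]]
        for c in kids[1:]:
            temp = add(temp, acc[c])
        acc[i] = mul(temp, values[i])
    total = acc[roots[0]]
    for r in roots[1:]:
        total = add(total, acc[r])
    return total


# ---------------------------------------------------------------------------
# Scalar transform evaluation
# ---------------------------------------------------------------------------


def _node_scalar_value(node: CompNode, omega: np.ndarray,
                       T: Optional[float]) -> float:
    if node.kind == "plain":
        denom = node.poly(omega)
        if denom == 0.0:
            raise DegenerateRateError("vanishing denominator q·r")
        return node.num / denom
    if T is None:
        raise ValueError("model has a discrete event: T is required")
    val = node.num * inverse_laplace_product(
        [p(omega) for p in node.poles], T
    )
    for f in node.factors:
        val /= f(omega)
    return val


def evaluate_laplace(source: Union[DemographicModel, StateGraph, ComputationalGraph],
                     omega: Sequence[float], T: Optional[float] = None, *,
                     phased: bool = False, rooted: bool = False) -> float:
    """Laplace transform of the joint branch-length distribution at ``ω``.

    For models with a discrete event the transform is the δ-inverted one,
    evaluated at event time ``T`` (which defaults to the model's event
    time).  At ``ω = 0`` the value is 1 (total probability).
    """
    if isinstance(source, DemographicModel):
        bts = BranchTypeSet(source, phased=phased, rooted=rooted)
        cg = ComputationalGraph(build_state_graph(source, bts))
    elif isinstance(source, StateGraph):
        cg = ComputationalGraph(source)
    else:
        cg = source
    model = cg.graph.model
    if model.event is not None and T is None:
        T = model.event.time
    omega = np.asarray(omega, dtype=float)
    values = [_node_scalar_value(n, omega, T) for n in cg.nodes]
    return propagate(
        cg.children, values, cg.roots, cg.topological_order()
    )
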