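"""Recursive generation of the coalescent state-space graph.

Each node is a state ``Ω = (Ω_1, ..., Ω_D)`` holding the extant ancestral
lineages per deme (plus a flag recording whether the discrete event has
fired).  Each edge carries an integer coefficient pair ``(p, q)`` over the
global rate vector ``r = (λ, δ, ω)``: the Laplace transform of the waiting
time for that transition, given the competition in the parent state, is
``(p·r)/(q·r)``.  The transform of the whole process is the sum over all
root-to-absorption paths of the product of edge transforms.
"""

from __future__ import annotations

import itertools
from collections import Counter, deque
from dataclasses import dataclass
from typing import Optional

from .model import (
    BranchTypeSet,
    DemographicModel,
    Lineage,
    MassMigration,
    UnsupportedModelError,
    lineage_sort_key,
    merge_lineages,
)

#: A state: per-deme sorted tuples of lineages, plus the discrete-event flag.
State = tuple[tuple[tuple[Lineage, ...], ...], bool]

COALESCENCE = "coalescence"
MIGRATION = "migration"
DISCRETE = "discrete"


@dataclass(frozen=True)
class RateLayout:
    """Fixed slot order of the global rate vector ``r = (λ, δ, ω)``.

    λ slots: one per deme (coalescence), then one per migration route.
    Then one δ slot if the model declares a discrete event, then one ω slot
    per branch type.
    """

    demes: tuple[str, ...]
    routes: tuple[tuple[str, str], ...]
    has_delta: bool
    n_types: int

    @property
    def n_lambda(self) -> int:
        return len(self.demes) + len(self.routes)

    @property
    def delta_slot(self) -> Optional[int]:
        return self.n_lambda if self.has_delta else None

    @property
    def omega_offset(self) -> int:
        return self.n_lambda + (1 if self.has_delta else 0)

    @property
    def size(self) -> int:
        return self.omega_offset + self.n_types

    def coalescence_slot(self, deme: str) -> int:
        return self.demes.index(deme)

    def migration_slot(self, route: tuple[str, str]) -> int:
        return len(self.demes) + self.routes.index(route)

    def names(self) -> list[str]:
        out = [f"coalescence[{d}]" for d in self.demes]
        out += [f"migration[{s}->{t}]" for s, t in self.routes]
        if self.has_delta:
            out.append("delta")
        out += [f"omega[{k}]" for k in range(self.n_types)]
        return out


@dataclass(frozen=True)
class EdgeEquation:
    """The coefficient pair of ``f* = (p·r)/(q·r)`` (one equation per edge).

    ``p`` is one-hot on the realized event's rate slot, scaled by the number
    of ways ``l`` the event can produce the child state; ``q`` counts every
    competing event's multiplicity plus, in the ω slots, the number of extant
    branches of each type in the parent state.
    """

    p: tuple[int, ...]
    q: tuple[int, ...]

    def __post_init__(self) -> None:
        nz = [i for i, v in enumerate(self.p) if v]
        if len(nz) != 1:
            raise ValueError("p must have exactly one non-zero entry")
        if self.p[nz[0]] > self.q[nz[0]]:
            raise ValueError("p's entry cannot exceed the matching q entry")

    @property
    def event_slot(self) -> int:
        return next(i for i, v in enumerate(self.p) if v)


@dataclass(frozen=True)
class Edge:
    parent: int
    child: int
    eq: int          # index into StateGraph.equations
    kind: str        # coalescence | migration | discrete


def _state_config(state: State) -> tuple[tuple[Lineage, ...], ...]:
    return state[0]


def _canonical(per_deme: list[list[Lineage]], fired: bool) -> State:
    return (
        tuple(tuple(sorted(d, key=lineage_sort_key)) for d in per_deme),
        fired,
    )


def coalescence_transitions(state: State, deme_idx: int) -> list[tuple[State, int]]:
    """Children of ``state`` under one coalescence in deme ``deme_idx``.

    All unordered lineage pairs are merged; identical children are grouped
    with summed multiplicity, so multiplicities add up to ``C(n_d, 2)``.
    """
    config, fired = state
    deme = config[deme_idx]
    if len(deme) < 2:
        return []
    children: Counter = Counter()
    for i, j in itertools.combinations(range(len(deme)), 2):
        merged = merge_lineages(deme[i], deme[j])
        rest = [l for k, l in enumerate(deme) if k not in (i, j)]
        per = [list(d) for d in config]
        per[deme_idx] = rest + [merged]
        children[_canonical(per, fired)] += 1
    return sorted(children.items(), key=lambda kv: kv[0])


def migration_transitions(state: State, source_idx: int,
                          dest_idx: int) -> list[tuple[State, int]]:
    """Children under one continuous migration event along a route.

    One transition per distinct lineage in the source deme, with multiplicity
    equal to that lineage's multiplicity (total = source deme size).
    """
    config, fired = state
    src = config[source_idx]
    children: Counter = Counter()
    for i in range(len(src)):
        per = [list(d) for d in config]
        moved = per[source_idx].pop(i)
        per[dest_idx].append(moved)
        children[_canonical(per, fired)] += 1
    return sorted(children.items(), key=lambda kv: kv[0])


def mass_migration_transition(state: State, source_idxs: tuple[int, ...],
                              dest_idx: int) -> Optional[State]:
    """Child of ``state`` under the discrete event, or ``None`` if it has
    already fired or would be a no-op (all source demes empty)."""
    config, fired = state
    if fired:
        return None
    if not any(config[i] for i in source_idxs):
        return None
    per = [list(d) for d in config]
    for i in source_idxs:
        per[dest_idx].extend(per[i])
        per[i] = []
    return _canonical(per, True)


class StateGraph:
    """Coalescent state-space graph with per-edge ``(p, q)`` equations.

    Nodes are states in BFS discovery order (node 0 = sampling state); edges
    are grouped transitions; ``equations`` is the deduplicated global table
    of ``(p, q)`` pairs, and each edge stores its equation index.
    """

    def __init__(self, model: DemographicModel, bts: BranchTypeSet) -> None:
        self.model = model
        self.bts = bts
        if bts.model is not model and bts.n_vector != tuple(
            model.samples[d] for d in model.sampled_demes
        ):
            raise ValueError("branch-type set does not match the model sample")
        self.layout = RateLayout(
            demes=model.demes,
            routes=tuple((r.source, r.dest) for r in model.migrations),
            has_delta=model.event is not None,
            n_types=len(bts),
        )
        self.states: list[State] = []
        self.edges: list[Edge] = []
        self.equations: list[EdgeEquation] = []
        self._eq_index: dict[tuple, int] = {}
        self.out_edges: list[list[int]] = []
        self._build()

    # -- construction -------------------------------------------------------

    def _root_state(self) -> State:
        per: list[list[Lineage]] = [[] for _ in self.model.demes]
        sampled = self.bts.sampled_demes
        if self.bts.phased:
            labels = self.model.sample_labels()
            for d, lst in zip(self.model.demes, per):
                lst.extend(frozenset([lab]) for lab in labels[d])
        else:
            for di, d in enumerate(self.model.demes):
                n = self.model.samples.get(d, 0)
                if n:
                    unit = tuple(
                        1 if s == d else 0 for s in sampled
                    )
                    lst = per[di]
                    lst.extend([unit] * n)
        return _canonical(per, False)

    def _route_active(self, route: tuple[str, str], fired: bool) -> bool:
        ev = self.model.event
        if ev is None or not fired:
            return True
        blocked = set(ev.sources)
        return route[0] not in blocked and route[1] not in blocked

    def _is_absorbing(self, state: State) -> bool:
        return sum(len(d) for d in state[0]) == 1

    def _omega_counts(self, state: State) -> tuple[int, ...]:
        counts = [0] * len(self.bts)
        for deme in state[0]:
            for lin in deme:
                counts[self.bts.index_of(lin)] += 1
        return tuple(counts)

    def _transitions(self, state: State):
        """All grouped transitions from ``state``: (kind, slot, child, l)."""
        config, fired = state
        model = self.model
        out = []
        for di, d in enumerate(model.demes):
            for child, l in coalescence_transitions(state, di):
                out.append((COALESCENCE, self.layout.coalescence_slot(d), child, l))
        for route in self.layout.routes:
            if not self._route_active(route, fired):
                continue
            si = model.demes.index(route[0])
            ti = model.demes.index(route[1])
            for child, l in migration_transitions(state, si, ti):
                out.append((MIGRATION, self.layout.migration_slot(route), child, l))
        if model.event is not None:
            src = tuple(model.demes.index(s) for s in model.event.sources)
            ti = model.demes.index(model.event.dest)
            child = mass_migration_transition(state, src, ti)
            if child is not None:
                out.append((DISCRETE, self.layout.delta_slot, child, 1))
        return out

    def _intern_eq(self, p: tuple[int, ...], q: tuple[int, ...]) -> int:
        key = (p, q)
        idx = self._eq_index.get(key)
        if idx is None:
            idx = len(self.equations)
            self.equations.append(EdgeEquation(p, q))
            self._eq_index[key] = idx
        return idx

    def _build(self) -> None:
        root = self._root_state()
        index = {root: 0}
        self.states.append(root)
        self.out_edges.append([])
        queue = deque([0])
        while queue:
            si = queue.popleft()
            state = self.states[si]
            if self._is_absorbing(state):
                continue
            transitions = self._transitions(state)
            if not transitions:
                raise UnsupportedModelError(
                    f"state {state} is a dead end: no event can reach the mrca"
                )
            q = [0] * self.layout.size
            for kind, slot, _child, l in transitions:
                q[slot] += l
            omega = self._omega_counts(state)
            off = self.layout.omega_offset
            for k, o in enumerate(omega):
                q[off + k] = o
            qt = tuple(q)
            for kind, slot, child, l in transitions:
                p = [0] * self.layout.size
                p[slot] = l
                eq = self._intern_eq(tuple(p), qt)
                ci = index.get(child)
                if ci is None:
                    ci = len(self.states)
                    index[child] = ci
                    self.states.append(child)
                    self.out_edges.append([])
                    queue.append(ci)
                self.out_edges[si].append(len(self.edges))
                self.edges.append(Edge(si, ci, eq, kind))

    # -- queries ------------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def absorbing_states(self) -> list[int]:
        return [i for i, s in enumerate(self.states) if self._is_absorbing(s)]

    def edge_has_delta(self, edge_idx: int) -> bool:
        """True if the edge's equation involves δ (in ``p`` or ``q``)."""
        ds = self.layout.delta_slot
        if ds is None:
            return False
        eq = self.equations[self.edges[edge_idx].eq]
        return eq.p[ds] > 0 or eq.q[ds] > 0

    @property
    def delta_edges(self) -> set[int]:
        """Edges realizing the discrete event (δ in ``p``)."""
        ds = self.layout.delta_slot
        if ds is None:
            return set()
        return {
            i for i, e in enumerate(self.edges)
            if self.equations[e.eq].p[ds] > 0
        }

    def topological_states(self) -> list[int]:
        """States in a topological order (parents before children)."""
        indeg = [0] * self.n_states
        for e in self.edges:
            indeg[e.child] += 1
        order, stack = [], [i for i, d in enumerate(indeg) if d == 0]
        while stack:
            s = stack.pop()
            order.append(s)
            for ei in self.out_edges[s]:
                c = self.edges[ei].child
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        if len(order) != self.n_states:
            raise UnsupportedModelError("state graph contains a cycle")
        return order

    def paths(self, max_paths: Optional[int] = 100_000) -> list[tuple[int, ...]]:
        """All root-to-absorption paths as edge-index sequences.

        The number of paths can grow much faster than the graph itself;
        ``max_paths`` guards against accidental blow-up.
        """
        out: list[tuple[int, ...]] = []
        stack: list[tuple[int, tuple[int, ...]]] = [(0, ())]
        while stack:
            s, pref = stack.pop()
            if self._is_absorbing(self.states[s]):
                out.append(pref)
                if max_paths is not None and len(out) > max_paths:
                    raise RuntimeError(f"more than {max_paths} paths")
                continue
            for ei in reversed(self.out_edges[s]):
                stack.append((self.edges[ei].child, pref + (ei,)))
        return sorted(out)

    def state_type_mask(self, state_idx: int) -> int:
        """Bitmask over branch types present in a state."""
        mask = 0
        for deme in self.states[state_idx][0]:
            for lin in deme:
                mask |= 1 << self.bts.index_of(lin)
        return mask

    def path_support_masks(self) -> set[int]:
        """Branch-type support (bitmask) of every root-to-absorption path.

        The support of a path is the union of branch types present in the
        states it visits (the absorbing state's mrca lineage carries no
        type).  Computed by dynamic programming over the DAG, so the result
        does not require enumerating paths.
        """
        reach: list[set[int]] = [set() for _ in range(self.n_states)]
        reach[0].add(0)
        supports: set[int] = set()
        for s in self.topological_states():
            if self._is_absorbing(self.states[s]):
                supports |= reach[s]
                continue
            mask = self.state_type_mask(s)
            contrib = {m | mask for m in reach[s]}
            for ei in self.out_edges[s]:
                reach[self.edges[ei].child] |= contrib
        return supports

    def to_dot(self) -> str:
        """DOT-format text export (node labels = Ω contents, edge labels =
        equation indices)."""
        def lab(state: State) -> str:
            config, fired = state
            demes = []
            for d, lins in zip(self.model.demes, config):
                parts = []
                for lin in lins:
                    if isinstance(lin, tuple):
                        parts.append("(" + ",".join(map(str, lin)) + ")")
                    else:
                        parts.append("{" + ",".join(sorted(lin)) + "}")
                demes.append(f"{d}:[" + " ".join(parts) + "]")
            sfx = " *" if fired else ""
            return "\\n".join(demes) + sfx

        lines = ["digraph statespace {"]
        for i, s in enumerate(self.states):
            lines.append(f'  n{i} [label="{lab(s)}"];')
        for ei, e in enumerate(self.edges):
            style = ' color="red"' if self.edge_has_delta(ei) else ""
            lines.append(
                f'  n{e.parent} -> n{e.child} [label="{e.eq}"{style}];'
            )
        lines.append("}")
        return "\n".join(lines)


def build_state_graph(model: DemographicModel, bts: BranchTypeSet) -> StateGraph:
    """Recursively generate the state-space graph for ``model``.

    Node 0 is the sampling configuration; states discovered breadth-first;
    identical transition outcomes are merged with multiplicity folded into
    ``p``.
    """
    return StateGraph(model, bts)
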