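"""Monte-Carlo oracle: simulation-based bSFS estimates.

Genealogies are drawn directly from the structured coalescent with the same
event semantics as the state-space graph (competing exponential waiting
times; the mass migration applied deterministically at its fixed time), and
per-branch-type total lengths are accumulated.  Since mutations of type
``i`` arrive as a Poisson process with rate ``θ/2`` per unit branch length,
each replicate contributes the product of Poisson probabilities at its
branch lengths; averaging over replicates estimates the exact bSFS without
ever placing mutations.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import stats

from .model import BranchTypeSet, DemographicModel
from .mutations import ConfigArray, array_layout, normalize_kmax
from .statespace import StateGraph, build_state_graph


@dataclass
class GenealogySample:
    """Per-branch-type total lengths of one simulated genealogy
    (coalescent time units)."""

    lengths: np.ndarray
    replicate: int


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    # stream derived from (seed, replicate): reps can grow without
    # reshuffling earlier draws
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(replicate))))


def simulate_branch_lengths(model: DemographicModel, bts: BranchTypeSet,
                            rng: np.random.Generator,
                            T: Optional[float] = None) -> np.ndarray:
    """One exact draw of per-branch-type total lengths.

    Waiting times are exponential with the state's total rate; the event is
    chosen proportionally to rates; the mass migration fires at time ``T``
    and, once fired, disables migration routes involving its source demes.
    """
    blocked: set[str] = set()
    if model.event is not None:
        if T is None:
            T = model.event.time
        if T is None:
            raise ValueError("model has a discrete event: T is required")
        src_idx = tuple(model.demes.index(d) for d in model.event.sources)
        dst_idx = model.demes.index(model.event.dest)
        blocked = set(model.event.sources)
    fired = model.event is None
    demes: list[list] = [[] for _ in model.demes]
    if bts.phased:
        labels = model.sample_labels()
        for di, d in enumerate(model.demes):
            demes[di].extend(frozenset([lab]) for lab in labels[d])
    else:
        sampled = bts.sampled_demes
        for di, d in enumerate(model.demes):
            n = model.samples.get(d, 0)
            if n:
                unit = tuple(1 if s == d else 0 for s in sampled)
                demes[di].extend([unit] * n)

    lengths = np.zeros(len(bts))
    t = 0.0
    while sum(len(d) for d in demes) > 1:
        rates = []
        events = []
        for di, d in enumerate(model.demes):
            k = len(demes[di])
            if k >= 2:
                rates.append(model.coalescence_rate(d) * k * (k - 1) / 2.0)
                events.append(("c", di, None))
        for route in model.migrations:
            if not fired or (
                route.source not in blocked and route.dest not in blocked
            ):
                si = model.demes.index(route.source)
                if demes[si]:
                    rates.append(route.rate * len(demes[si]))
                    events.append(("m", si, model.demes.index(route.dest)))
        total = sum(rates)
        if total == 0.0 and fired:
            raise RuntimeError("simulation stalled: no event has positive rate")
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        if not fired and t + wait >= T:
            dt = T - t
            for d in demes:
                for lin in d:
                    lengths[bts.index_of(lin)] += dt
            for si in src_idx:
                demes[dst_idx].extend(demes[si])
                demes[si] = []
            fired = True
            t = T
            continue
        for d in demes:
            for lin in d:
                lengths[bts.index_of(lin)] += wait
        t += wait
        kind, a, b = events[
            rng.choice(len(events), p=np.asarray(rates) / total)
        ]
        if kind == "c":
            d = demes[a]
            i, j = rng.choice(len(d), size=2, replace=False)
            if bts.phased:
                merged = d[i] | d[j]
            else:
                merged = tuple(x + y for x, y in zip(d[i], d[j]))
            demes[a] = [d[k] for k in range(len(d)) if k not in (i, j)] + [merged]
        else:
            i = rng.integers(len(demes[a]))
            demes[b].append(demes[a].pop(i))
    return lengths


def _poisson_vectors(lengths: np.ndarray, theta: float,
                     kmax: tuple[int, ...]) -> list[np.ndarray]:
    """Per type: pmf at 0..kmax plus the ``>kmax`` tail; each sums to 1."""
    out = []
    for t_i, k_i in zip(lengths, kmax):
        mu = 0.5 * theta * t_i
        ks = np.arange(k_i + 1)
        pmf = stats.poisson.pmf(ks, mu)
        tail = stats.poisson.sf(k_i, mu)
        out.append(np.concatenate([pmf, [tail]]))
    return out


def estimate_bsfs(source: Union[DemographicModel, StateGraph], theta: float,
                  kmax, reps: int, seed: int, T: Optional[float] = None, *,
                  phased: bool = False, rooted: bool = False) -> ConfigArray:
    """Monte-Carlo estimate of the bSFS with per-entry standard errors.

    Each replicate's outer product of per-type Poisson vectors sums to one,
    so the averaged estimate does too.  Standard errors are the replicate
    standard deviation over ``sqrt(reps)``.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    if isinstance(source, DemographicModel):
        bts = BranchTypeSet(source, phased=phased, rooted=rooted)
        graph = build_state_graph(source, bts)
    else:
        graph = source
        bts = graph.bts
    model = graph.model
    kmax = normalize_kmax(kmax, len(bts))
    shape = tuple(k + 2 for k in kmax)
    mean = np.zeros(shape)
    m2 = np.zeros(shape)
    for r in range(reps):
        rng = _replicate_rng(seed, r)
        lengths = simulate_branch_lengths(model, bts, rng, T=T)
        vecs = _poisson_vectors(lengths, theta, kmax)
        table = vecs[0]
        for v in vecs[1:]:
            table = np.multiply.outer(table, v)
        delta = table - mean
        mean += delta / (r + 1)
        m2 += delta * (table - mean)
    se = np.sqrt(m2 / reps / max(reps - 1, 1))
    return ConfigArray(
        values=mean, kmax=kmax, bts=bts,
        layout=array_layout(kmax, graph), se=se,
        meta={"theta": theta, "T": T, "mode": "mc", "reps": reps, "seed": seed},
    )
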