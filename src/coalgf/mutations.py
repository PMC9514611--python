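"""Mutation-configuration bookkeeping: array layout, structural zeros,
equiprobable classes.

A mutation configuration is a vector ``k = (k_1..k_K)`` of per-branch-type
mutation counts within a non-recombining block, truncated at ``kmax_i`` per
type with the value ``kmax_i + 1`` standing for "more than ``kmax_i``".
Some branch types can never be observed jointly on a single genealogy;
configurations marking such combinations are *structural zeros* and are
pre-determined from the state graph rather than computed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import prod
from typing import Iterator, Optional, Sequence

import numpy as np

from .model import BranchTypeSet
from .statespace import StateGraph

#: Masked dense storage is used up to this many slots; above it, only the
#: compatible cells are indexable (hash map).
DENSE_LIMIT = 10_000_000


def _downward_closure(masks: Sequence[int]) -> set[int]:
    closed: set[int] = set()
    for m in masks:
        sub = m
        while True:
            closed.add(sub)
            if sub == 0:
                break
            sub = (sub - 1) & m
    return closed


def compatible_supports(graph: StateGraph) -> set[int]:
    """All branch-type sets (bitmasks) that can jointly carry mutations.

    A set is compatible iff it is contained in the branch types present
    along at least one root-to-absorption path — i.e. in the clade set of
    at least one realizable genealogy.  Computed per path support by
    dynamic programming and closed downward (compatibility is monotone
    under support shrinkage).
    """
    return _downward_closure(sorted(graph.path_support_masks()))


def config_support(config: Sequence[int]) -> int:
    return sum(1 << i for i, k in enumerate(config) if k > 0)


def normalize_kmax(kmax, n_types: int) -> tuple[int, ...]:
    """Broadcast a scalar kmax to all branch types; validate a vector."""
    if np.isscalar(kmax):
        kmax = (int(kmax),) * n_types
    kmax = tuple(int(k) for k in kmax)
    if len(kmax) != n_types:
        raise ValueError(f"kmax must have {n_types} entries, got {len(kmax)}")
    if any(k < 0 for k in kmax):
        raise ValueError("kmax entries must be non-negative")
    return kmax


@dataclass
class ArrayLayout:
    """Sparsity bookkeeping for the configuration array.

    ``shape`` is ``(kmax_i + 2)`` per branch type; ``supports`` the
    downward-closed family of compatible branch-type sets.  Incompatible
    slots always read as exact zero.
    """

    kmax: tuple[int, ...]
    supports: set[int]

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(k + 2 for k in self.kmax)

    @property
    def n_slots(self) -> int:
        return prod(self.shape)

    @property
    def n_compatible(self) -> int:
        """Number of compatible configurations (including residual bins)."""
        total = 0
        for s in self.supports:
            total += prod(
                self.kmax[i] + 1 for i in range(len(self.kmax)) if s >> i & 1
            )
        return total

    def is_compatible(self, config: Sequence[int]) -> bool:
        return config_support(config) in self.supports

    def mask(self) -> np.ndarray:
        """Dense boolean mask of compatible cells (refuses huge arrays)."""
        if self.n_slots > DENSE_LIMIT:
            raise MemoryError(
                f"dense mask of {self.n_slots} slots exceeds the storage limit"
            )
        m = np.zeros(self.shape, dtype=bool)
        for config in self.iter_compatible():
            m[config] = True
        return m

    def iter_compatible(self) -> Iterator[tuple[int, ...]]:
        """All compatible configurations, support by support."""
        K = len(self.kmax)
        for s in sorted(self.supports):
            idx = [i for i in range(K) if s >> i & 1]
            ranges = [range(1, self.kmax[i] + 2) for i in idx]
            for vals in itertools.product(*ranges):
                config = [0] * K
                for i, v in zip(idx, vals):
                    config[i] = v
                yield tuple(config)


def array_layout(kmax, graph: StateGraph) -> ArrayLayout:
    """Layout (shape + compatibility) for a graph and truncation vector."""
    kmax = normalize_kmax(kmax, len(graph.bts))
    return ArrayLayout(kmax=kmax, supports=compatible_supports(graph))


def compatible_configurations(graph: StateGraph, kmax) -> Iterator[tuple[int, ...]]:
    """Iterate configurations with non-zero probability (the all-zero
    configuration first)."""
    return array_layout(kmax, graph).iter_compatible()


def count_compatible(graph: StateGraph, kmax) -> int:
    return array_layout(kmax, graph).n_compatible


# ---------------------------------------------------------------------------
# Equiprobable configuration classes (phased samples)
# ---------------------------------------------------------------------------


def _type_permutation(bts: BranchTypeSet, label_map: dict[str, str]) -> list[int]:
    out = []
    for t in bts.types:
        image = frozenset(label_map[x] for x in t)
        out.append(bts._index[bts.fold(image)])
    return out


def equiprobable_classes(bts: BranchTypeSet, kmax) -> list[list[tuple[int, ...]]]:
    """Partition configurations into classes of equal probability.

    With phased samples, permuting the labels of samples drawn from the same
    deme leaves the model invariant, so configurations related by the induced
    branch-type permutation share one probability.  Without phase the deme
    labelling has already collapsed this symmetry and every class is a
    singleton.
    """
    kmax = normalize_kmax(kmax, len(bts))
    shape = tuple(k + 2 for k in kmax)
    all_configs = list(itertools.product(*(range(s) for s in shape)))
    if not bts.phased:
        return [[c] for c in all_configs]
    labels = bts.model.sample_labels()
    groups = [labels[d] for d in bts.sampled_demes]
    perms = []
    for combo in itertools.product(*(itertools.permutations(g) for g in groups)):
        label_map = {}
        for orig, permuted in zip(groups, combo):
            label_map.update(dict(zip(orig, permuted)))
        perms.append(_type_permutation(bts, label_map))
    orbits: dict[tuple[int, ...], list[tuple[int, ...]]] = {}
    for config in all_configs:
        images = set()
        for tp in perms:
            img = [0] * len(config)
            for i, k in enumerate(config):
                img[tp[i]] = k
            images.add(tuple(img))
        rep = min(images)
        orbits.setdefault(rep, [])
        if config not in orbits[rep]:
            orbits[rep].append(config)
    return [sorted(v) for _, v in sorted(orbits.items())]


# ---------------------------------------------------------------------------
# Probability container
# ---------------------------------------------------------------------------


@dataclass
class ConfigArray:
    """Probabilities over all block-wise mutation configurations.

    ``values`` has one axis per branch type with sizes ``kmax_i + 2``; the
    last bin of each axis is the ``> kmax_i`` residual.  Optionally carries
    per-entry Monte-Carlo standard errors.
    """

    values: np.ndarray
    kmax: tuple[int, ...]
    bts: BranchTypeSet
    layout: Optional[ArrayLayout] = None
    se: Optional[np.ndarray] = None
    meta: Optional[dict] = None

    def total(self) -> float:
        return float(self.values.sum())

    def __getitem__(self, config) -> float:
        return float(self.values[tuple(config)])

    def to_tsv(self, path=None, include_zero: bool = False) -> Optional[str]:
        """One row per (compatible) configuration; ``>kmax`` printed as
        ``kmax+1``.  Header lines (``#``) carry the branch-type order."""
        lines = [
            "# branch_types\t" + "\t".join(self.bts.header()),
            "# phased=%s rooted=%s kmax=%s"
            % (self.bts.phased, self.bts.rooted, ",".join(map(str, self.kmax))),
        ]
        if self.meta:
            for k, v in sorted(self.meta.items()):
                lines.append(f"# {k}={v}")
        cols = [f"k_{i}" for i in range(len(self.kmax))] + ["probability"]
        if self.se is not None:
            cols.append("se")
        lines.append("\t".join(cols))
        if self.layout is not None and not include_zero:
            configs = sorted(self.layout.iter_compatible())
        else:
            configs = list(
                itertools.product(*(range(k + 2) for k in self.kmax))
            )
        for c in configs:
            row = list(map(str, c)) + [repr(float(self.values[c]))]
            if self.se is not None:
                row.append(repr(float(self.se[c])))
            lines.append("\t".join(row))
        text = "\n".join(lines) + "\n"
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None
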