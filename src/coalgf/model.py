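"""Demographic models, samples, lineages and the branch-type coordinate system.

A demographic model is a set of demes with relative effective sizes, sample
counts, unidirectional continuous migration routes, and at most one discrete
event (a mass migration realizing a population split, viewed backwards in
time).  Time is measured in coalescent units of ``2 * Ne_ref`` generations,
so the pairwise coalescence rate in deme ``d`` is ``Ne_ref / Ne_d``.

Lineages are labelled by the samples they subtend.  With phased samples each
sample carries a unique label; without phase information samples are labelled
by the deme they were collected from, so a lineage reduces to a vector of
per-deme subtended counts.  Every (non-root) lineage maps to a *branch type*;
discarding root information folds each type with its complement relative to
the full sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union


class InvalidModelError(ValueError):
    """Raised when a demographic model violates a structural constraint."""


class UnsupportedModelError(ValueError):
    """Raised for models outside the supported class (e.g. cyclic migration)."""


@dataclass(frozen=True)
class MigrationRoute:
    """Unidirectional continuous migration at constant (backwards) rate.

    ``rate`` is the per-lineage migration rate in coalescent time units
    (``2 * Ne_ref * m`` for a per-generation backwards fraction ``m``).
    """

    source: str
    dest: str
    rate: float

    def __post_init__(self) -> None:
        if self.source == self.dest:
            raise InvalidModelError("migration route must join distinct demes")
        if not self.rate > 0:
            raise InvalidModelError("migration rate must be strictly positive")


@dataclass(frozen=True)
class MassMigration:
    """Discrete event moving all lineages from ``sources`` into ``dest``.

    Backwards in time this realizes a population split: the derived demes
    (``sources``) merge into the ancestral deme ``dest`` at time ``time``.
    A single-source event is an ordinary one-off mass migration.  ``time``
    may be left unset and supplied at evaluation instead.
    """

    sources: tuple[str, ...]
    dest: str
    time: Optional[float] = None

    def __init__(self, sources: Union[str, Sequence[str]], dest: str,
                 time: Optional[float] = None) -> None:
        if isinstance(sources, str):
            sources = (sources,)
        object.__setattr__(self, "sources", tuple(sources))
        object.__setattr__(self, "dest", dest)
        object.__setattr__(self, "time", time)
        if dest in self.sources:
            raise InvalidModelError("event destination cannot be a source deme")
        if len(set(self.sources)) != len(self.sources) or not self.sources:
            raise InvalidModelError("event sources must be distinct and non-empty")
        if time is not None and time < 0:
            raise InvalidModelError("event time must be non-negative")


@dataclass(frozen=True)
class DemographicModel:
    """Structured-coalescent model specification.

    Parameters
    ----------
    demes:
        Ordered deme identifiers.
    samples:
        Per-deme sample counts ``n_d`` (missing demes default to 0).
    relative_sizes:
        ``Ne_d / Ne_ref`` per deme (default 1).  The pairwise coalescence
        rate in deme ``d`` is the reciprocal, ``Ne_ref / Ne_d``.
    migrations:
        Continuous unidirectional migration routes.  Routes must not form a
        directed cycle (cyclic state spaces are unsupported).
    event:
        Optional discrete :class:`MassMigration`; at most one.
    reference:
        Identifier of the reference deme (defaults to the first deme).
    """

    demes: tuple[str, ...]
    samples: dict[str, int] = field(default_factory=dict)
    relative_sizes: dict[str, float] = field(default_factory=dict)
    migrations: tuple[MigrationRoute, ...] = ()
    event: Optional[MassMigration] = None
    reference: Optional[str] = None

    def __init__(self, demes: Sequence[str],
                 samples: Optional[dict[str, int]] = None,
                 relative_sizes: Optional[dict[str, float]] = None,
                 migrations: Iterable[Union[MigrationRoute, tuple]] = (),
                 event: Optional[MassMigration] = None,
                 reference: Optional[str] = None) -> None:
        demes = tuple(demes)
        if len(set(demes)) != len(demes):
            raise InvalidModelError("deme identifiers must be unique")
        samples = dict(samples or {})
        relative_sizes = dict(relative_sizes or {})
        routes = tuple(
            m if isinstance(m, MigrationRoute) else MigrationRoute(*m)
            for m in migrations
        )
        object.__setattr__(self, "demes", demes)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "relative_sizes", relative_sizes)
        object.__setattr__(self, "migrations", routes)
        object.__setattr__(self, "event", event)
        object.__setattr__(self, "reference", reference or demes[0])
        self._validate()

    def _validate(self) -> None:
        for d in self.samples:
            if d not in self.demes:
                raise InvalidModelError(f"samples given for unknown deme {d!r}")
        for d, c in self.samples.items():
            if c < 0:
                raise InvalidModelError("sample counts must be non-negative")
        if self.total_samples < 2:
            raise InvalidModelError("total sample size must be at least 2")
        for d, s in self.relative_sizes.items():
            if d not in self.demes:
                raise InvalidModelError(f"size given for unknown deme {d!r}")
            if not s > 0:
                raise InvalidModelError("relative sizes must be strictly positive")
        if self.reference not in self.demes:
            raise InvalidModelError(f"unknown reference deme {self.reference!r}")
        for r in self.migrations:
            if r.source not in self.demes or r.dest not in self.demes:
                raise InvalidModelError(f"migration route {r} names unknown deme")
        if len({(r.source, r.dest) for r in self.migrations}) != len(self.migrations):
            raise InvalidModelError("duplicate migration route")
        if self.event is not None:
            for d in (*self.event.sources, self.event.dest):
                if d not in self.demes:
                    raise InvalidModelError(f"event names unknown deme {d!r}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        adj: dict[str, set[str]] = {d: set() for d in self.demes}
        for r in self.migrations:
            adj[r.source].add(r.dest)
        seen: dict[str, int] = {}  # 1 = on stack, 2 = done

        def visit(d: str) -> None:
            seen[d] = 1
            for e in adj[d]:
                if seen.get(e) == 1:
                    raise UnsupportedModelError(
                        "migration routes form a directed cycle; cyclic state "
                        "spaces (e.g. bi-directional migration) are unsupported"
                    )
                if e not in seen:
                    visit(e)
            seen[d] = 2

        for d in self.demes:
            if d not in seen:
                visit(d)

    # -- derived quantities -------------------------------------------------

    @property
    def total_samples(self) -> int:
        return sum(self.samples.values())

    @property
    def sampled_demes(self) -> tuple[str, ...]:
        """Demes holding at least one sample, in deme order."""
        return tuple(d for d in self.demes if self.samples.get(d, 0) > 0)

    def coalescence_rate(self, deme: str) -> float:
        """Pairwise coalescence rate ``Ne_ref / Ne_d`` in deme ``deme``."""
        return 1.0 / self.relative_sizes.get(deme, 1.0)

    def sample_labels(self) -> dict[str, tuple[str, ...]]:
        """Deme-major phased sample labels (``a1, a2, ..., b1, ...``)."""
        out = {}
        for d in self.demes:
            sym = d.lower()
            out[d] = tuple(f"{sym}{i + 1}" for i in range(self.samples.get(d, 0)))
        return out


# ---------------------------------------------------------------------------
# Lineages
# ---------------------------------------------------------------------------

#: A lineage is identified by what it subtends: a per-sampled-deme count
#: vector (unphased) or a frozenset of unique sample labels (phased).
Lineage = Union[tuple[int, ...], frozenset]


def merge_lineages(a: Lineage, b: Lineage) -> Lineage:
    """Lineage subtending the union of two coalescing lineages."""
    if isinstance(a, tuple):
        return tuple(x + y for x, y in zip(a, b))
    return a | b


def lineage_sort_key(lin: Lineage):
    if isinstance(lin, tuple):
        return lin
    return tuple(sorted(lin))


class RootLineageError(ValueError):
    """The lineage subtends the full sample: it is the mrca branch and has no
    branch type."""


class BranchTypeSet:
    """Canonical, deterministically ordered set of branch types.

    Branch types are indexed lexicographically on the per-deme subtended-count
    vector (unphased) or on the sorted sample-label tuple (phased).  With
    ``rooted=False`` each type is folded with its complement relative to the
    full sample and the lexicographically smaller member represents the class.
    """

    def __init__(self, model: DemographicModel, phased: bool = False,
                 rooted: bool = False) -> None:
        if model.total_samples < 2:
            raise InvalidModelError("branch types require a sample of size >= 2")
        self.model = model
        self.phased = bool(phased)
        self.rooted = bool(rooted)
        self.sampled_demes = model.sampled_demes
        self.n_vector = tuple(model.samples[d] for d in self.sampled_demes)

        if phased:
            labels = model.sample_labels()
            self.all_labels = tuple(
                lab for d in self.sampled_demes for lab in labels[d]
            )
            full = frozenset(self.all_labels)
            unfolded = [
                frozenset(c)
                for r in range(1, len(self.all_labels))
                for c in itertools.combinations(self.all_labels, r)
            ]
            self._full = full
        else:
            ranges = [range(n + 1) for n in self.n_vector]
            unfolded = [
                v for v in itertools.product(*ranges)
                if any(v) and v != self.n_vector
            ]
            self._full = self.n_vector

        self.unfolded_count = len(unfolded)
        reps = sorted({self._fold(t) for t in unfolded}, key=lineage_sort_key)
        self.types: tuple[Lineage, ...] = tuple(reps)
        self._index = {t: i for i, t in enumerate(reps)}

    def __len__(self) -> int:
        return len(self.types)

    def _complement(self, t: Lineage) -> Lineage:
        if self.phased:
            return self._full - t
        return tuple(n - x for n, x in zip(self.n_vector, t))

    def _fold(self, t: Lineage) -> Lineage:
        if self.rooted:
            return t
        c = self._complement(t)
        return min(t, c, key=lineage_sort_key)

    def fold(self, t: Lineage) -> Lineage:
        """Canonical (folded) representative of an unfolded type."""
        return self._fold(t)

    def lineage_key(self, lineage: Lineage) -> Lineage:
        """Canonicalize a raw lineage (phased set / unphased count vector)."""
        if self.phased:
            return frozenset(lineage)
        return tuple(lineage)

    def index_of(self, lineage: Lineage) -> int:
        """Branch-type index of a lineage.

        Raises :class:`RootLineageError` for the full-sample (mrca) lineage
        and ``KeyError`` for malformed lineages.
        """
        key = self.lineage_key(lineage)
        if key == self._full:
            raise RootLineageError(
                "lineage subtends the full sample; the mrca branch has no type"
            )
        return self._index[self._fold(key)]

    def header(self) -> list[str]:
        """Human-readable names, in index order, for output headers."""
        names = []
        for t in self.types:
            if self.phased:
                names.append("{" + ",".join(sorted(t)) + "}")
            else:
                names.append("(" + ",".join(map(str, t)) + ")")
        return names


def enumerate_branch_types(model: DemographicModel, phased: bool = False,
                           rooted: bool = False) -> BranchTypeSet:
    """Enumerate the canonical branch types for a model's sample.

    For phased, rooted samples of size ``n`` there are ``2**n - 2`` types;
    folding (``rooted=False``) merges complementary types pairwise.
    """
    return BranchTypeSet(model, phased=phased, rooted=rooted)


def branch_type_index(lineage: Lineage, bts: BranchTypeSet) -> int:
    """Index of the branch type a lineage belongs to (see
    :meth:`BranchTypeSet.index_of`)."""
    return bts.index_of(lineage)
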