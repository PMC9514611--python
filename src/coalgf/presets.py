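"""Canonical two-population models used throughout the tests and examples."""

from __future__ import annotations

from .model import DemographicModel, MassMigration


def two_population_migration(n_per_deme: int, migration_rate: float = 1.0,
                             size_ratio: float = 1.0) -> DemographicModel:
    """Two demes, ``n`` unphased samples each, unidirectional A→B migration
    (backwards in time) at a constant rate, no discrete events.

    ``size_ratio`` is ``Ne_B / Ne_A`` with A the reference.
    """
    return DemographicModel(
        demes=("A", "B"),
        samples={"A": n_per_deme, "B": n_per_deme},
        relative_sizes={"A": 1.0, "B": size_ratio},
        migrations=[("A", "B", migration_rate)],
    )


def im_model(n_per_deme: int, migration_rate: float = 1.0,
             split_time: float = 1.0, size_a: float = 1.0,
             size_b: float = 1.0, size_anc: float = 1.0) -> DemographicModel:
    """Isolation-with-migration: demes A and B split from the ancestral
    population AB at ``split_time`` (backwards: both merge into AB), with
    unidirectional A→B migration (backwards in time) until the split.

    Sizes are relative to the reference deme A; times and rates are in
    coalescent units of ``2·Ne_A`` generations.
    """
    return DemographicModel(
        demes=("A", "B", "AB"),
        samples={"A": n_per_deme, "B": n_per_deme},
        relative_sizes={"A": size_a, "B": size_b, "AB": size_anc},
        migrations=[("A", "B", migration_rate)],
        event=MassMigration(("A", "B"), "AB", time=split_time),
    )


def im_benchmark(n_per_deme: int = 2) -> tuple[DemographicModel, float]:
    """The accuracy-benchmark IM fixture and its θ.

    Absolute parameters: ``Ne_AB = 1.5e6``, ``Ne_A = 1.3e6`` (reference),
    ``Ne_B = 0.6e6``, per-generation backwards migration fraction
    ``m = 7e-7`` from A to B, split ``T = 1e7`` generations ago,
    ``θ = 1.152`` per block.  Converted to coalescent units of
    ``2·Ne_A`` generations: per-lineage migration rate ``2·Ne_A·m``,
    split time ``T / (2·Ne_A)``.
    """
    ne_a, ne_b, ne_anc = 1.3e6, 0.6e6, 1.5e6
    m_gen, t_gen, theta = 7e-7, 1e7, 1.152
    model = im_model(
        n_per_deme,
        migration_rate=2 * ne_a * m_gen,
        split_time=t_gen / (2 * ne_a),
        size_b=ne_b / ne_a,
        size_anc=ne_anc / ne_a,
    )
    return model, theta
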