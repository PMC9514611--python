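import numpy as np
import pytest

from coalgf import (
    DemographicModel,
    GfEvaluator,
    MassMigration,
    enumerate_branch_types,
)
from coalgf.presets import im_benchmark, im_model, two_population_migration


@pytest.fixture(scope="session")
def single_pop2():
    """One deme, two unphased samples: the analytically solvable case."""
    return DemographicModel(["A"], samples={"A": 2})


@pytest.fixture(scope="session")
def toy_model():
    """Two unphased samples in A, one in B; single mass migration B→A."""
    return DemographicModel(
        ["A", "B"], samples={"A": 2, "B": 1},
        event=MassMigration("B", "A", time=0.7),
    )


@pytest.fixture(scope="session")
def mig2_eval():
    return GfEvaluator(two_population_migration(2))


@pytest.fixture(scope="session")
def im2_eval():
    return GfEvaluator(im_model(2, migration_rate=0.8, split_time=1.3,
                                size_b=0.5, size_anc=1.2))


@pytest.fixture(scope="session")
def benchmark_fixture():
    model, theta = im_benchmark(2)
    return GfEvaluator(model), theta


@pytest.fixture(scope="session")
def toy_eval(toy_model):
    return GfEvaluator(toy_model)
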