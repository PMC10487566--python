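import numpy as np
import pytest

from msrisk import (
    FEMALE,
    MALE,
    apply_exclusions,
    default_memberships,
    default_model,
    fixture_700,
    make_capacity,
    reference_capacity,
)
from msrisk.capacity import all_subsets, repair_monotonicity


@pytest.fixture(scope="session")
def memberships():
    return default_memberships()


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def female_capacity():
    return reference_capacity(FEMALE)


@pytest.fixture(scope="session")
def male_capacity():
    return reference_capacity(MALE)


@pytest.fixture(scope="session")
def fixture_cohort():
    return fixture_700()


@pytest.fixture(scope="session")
def retained_cohort(fixture_cohort):
    retained, _ = apply_exclusions(fixture_cohort)
    return retained


def random_capacity(rng: np.random.Generator, n_factors: int = 4):
    """A random monotone capacity: uniform draws lifted by running maximum."""
    table = {s: float(rng.uniform(0, 1)) for s in all_subsets(n_factors)}
    table[frozenset()] = 0.0
    return make_capacity(repair_monotonicity(table), n_factors=n_factors,
                         label="random")


def random_risk_vector(rng: np.random.Generator, n: int = 4):
    return tuple(float(v) for v in rng.uniform(0, 1, size=n))
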