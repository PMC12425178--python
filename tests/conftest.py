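import numpy as np
import pytest

import agemix as am


@pytest.fixture
def unit_interval() -> am.Partition:
    return am.make_partition([0.0, 10.0])


@pytest.fixture
def halves() -> am.Partition:
    return am.make_partition([0.0, 5.0, 10.0])


@pytest.fixture
def uniform_density() -> am.FeatureFunction:
    """ρ(x) = 0.1 on [0, 10]."""
    return am.FeatureFunction(
        lambda x: np.full_like(np.asarray(x, dtype=float), 0.1),
        (0.0, 10.0), is_density=True,
    )


@pytest.fixture
def triangular_density() -> am.FeatureFunction:
    """ρ(x) ∝ x on [0, 10], normalised (ρ = x/50)."""
    return am.FeatureFunction(
        lambda x: np.asarray(x, dtype=float) / 50.0, (0.0, 10.0), is_density=True,
    )


@pytest.fixture
def identity_parameter() -> am.FeatureFunction:
    """parameter(x) = x on [0, 10]."""
    return am.FeatureFunction(lambda x: np.asarray(x, dtype=float), (0.0, 10.0))


@pytest.fixture
def constant_parameter() -> am.FeatureFunction:
    """parameter(x) = 0.3 on [0, 10]."""
    return am.FeatureFunction(
        lambda x: np.full_like(np.asarray(x, dtype=float), 0.3), (0.0, 10.0)
    )


@pytest.fixture(scope="session")
def demo_model() -> am.Partition:
    """The four broad age groups: pre-school, school, working, elderly."""
    return am.make_partition([0, 5, 20, 65, 101])


@pytest.fixture(scope="session")
def demo_output() -> am.Partition:
    """1-year output groups, 0 through 100+."""
    return am.make_partition(np.arange(0, 102))


@pytest.fixture(scope="session")
def hic_demography() -> am.SyntheticDemography:
    return am.make_demography("rectangular", seed=1)


@pytest.fixture(scope="session")
def lmic_demography() -> am.SyntheticDemography:
    return am.make_demography("young", seed=1)


@pytest.fixture(scope="session")
def hic_life_table() -> am.LifeTable:
    return am.make_life_table("rectangular")


@pytest.fixture(scope="session")
def lmic_life_table() -> am.LifeTable:
    return am.make_life_table("young")
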