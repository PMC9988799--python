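import numpy as np
import pytest

from survexpect import (
    GompertzParams,
    LifeTable,
    default_config,
    generate_cohort,
    generate_life_table,
)


@pytest.fixture(scope="session")
def tiny_table() -> LifeTable:
    """Three-row table with an absorbing terminal age, hand-checkable."""
    return LifeTable(ages=np.array([60, 61, 62]), qx=np.array([0.01, 0.012, 1.0]))


@pytest.fixture(scope="session")
def gompertz_table() -> LifeTable:
    return generate_life_table(GompertzParams())


@pytest.fixture(scope="session")
def small_cohort(gompertz_table):
    """Quarter-scale default synthetic cohort (about 1,400 records)."""
    config = default_config(seed=20240915, size_scale=0.25)
    return config, generate_cohort(config, gompertz_table)
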