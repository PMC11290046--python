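import numpy as np
import pytest

from gp4pg.demography import (
    DemographicModel,
    Ecodeme,
    MigrationDecayParams,
    SoftSplit,
)
from gp4pg.simulate import GenomeSpec


@pytest.fixture
def decay():
    return MigrationDecayParams(m_max=0.01, m_min=0.001, t_split=1000.0)


@pytest.fixture
def two_pop_model(decay):
    """Two leaf ecodemes (2 topodemes each) merging into a root at t=1000."""
    return DemographicModel(
        ecodemes=[
            Ecodeme("A", position=0, n_topodemes=2, ne_per_topodeme=2000.0),
            Ecodeme("B", position=200, n_topodemes=2, ne_per_topodeme=2000.0),
            Ecodeme("R", position=1, n_topodemes=1, ne_per_topodeme=3000.0),
        ],
        events=[SoftSplit("R", "A", "B", 1000.0, decay)],
        sampling={"A": 2, "B": 2},
    )


@pytest.fixture
def single_pop_model():
    return DemographicModel(
        ecodemes=[Ecodeme("A", position=0, n_topodemes=1, ne_per_topodeme=5000.0)],
        sampling={"A": 10},
        internal_migration=0.0,
    )


@pytest.fixture
def small_genome():
    return GenomeSpec(n_blocks=30, block_length=10_000)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
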