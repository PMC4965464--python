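import numpy as np
import pytest

from lrrmeta.io import build_effect_table
from lrrmeta.simulate import SimulationConfig, generate_literature


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_literature():
    """A modest synthetic literature shared across read-only tests."""
    cfg = SimulationConfig(
        n_studies=120,
        mu=0.4,
        tau2=0.04,
        moderator_slopes={"colonization_pct": 0.005},
        missing_n_fraction=0.05,
        zero_value_rate=0.01,
        seed=77,
    )
    table, truth = generate_literature(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_effects(small_literature):
    _, table, _ = small_literature
    eff, log = build_effect_table(table)
    return eff, log
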