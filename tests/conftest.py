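import numpy as np
import pandas as pd
import pytest

from spatbiv import Dataset, SimConfig, make_lattice_zones, simulate_dataset


@pytest.fixture
def toy_dataset():
    """Four records over two zones, one declared covariate."""
    df = pd.DataFrame(
        {
            "anc": [1, 1, 0, 0],
            "dc": [1, 0, 0, 0],
            "zone": ["A", "A", "B", "B"],
            "year": ["2000"] * 4,
            "weight": [2.0, 1.0, 1.0, 1.0],
            "wealth": ["poor", "rich", "poor", "rich"],
        }
    )
    return Dataset(df, schema={"wealth": ["poor", "middle", "rich"]})


@pytest.fixture
def lattice33():
    return make_lattice_zones(3, 3)


@pytest.fixture
def sim_small():
    """Small simulated survey shared by the heavier model/pipeline tests."""
    cfg = SimConfig(lattice=(3, 3), n_per_zone_year=60, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
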