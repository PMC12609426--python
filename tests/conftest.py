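import datetime as dt

import numpy as np
import pandas as pd
import pytest

from sifmstws import RegistryConfig, WorldConfig, generate_world, train_registry
from sifmstws.experiments import make_processed_table

FAST_GRID = [{"max_iter": 60, "learning_rate": 0.2, "max_leaf_nodes": 15}]


@pytest.fixture(scope="session")
def mini_world():
    """Small single-year world straddling the equator (20 x 40 cells)."""
    cfg = WorldConfig(
        lat_min=-0.5, lat_max=0.5, lon_min=0.0, lon_max=2.0, years=(2023,)
    )
    return generate_world(cfg, seed=7)


@pytest.fixture(scope="session")
def mini_table(mini_world):
    """Processed, labeled training table for one DOY window."""
    return make_processed_table(mini_world, (225,), seed=7)


@pytest.fixture(scope="session")
def mini_registry(mini_table):
    """Fleet over one DOY with relaxed sample rules (small-world unit tests)."""
    strata = tuple(sorted(int(s) for s in mini_table["stratum"].unique()))
    rc = RegistryConfig(
        algorithm="gbt", param_grid=FAST_GRID, folds=2,
        cap=1500, min_n=200, seed=7, doys=(225,), strata=strata,
    )
    return train_registry(mini_table, rc)


@pytest.fixture()
def simple_footprints():
    """Deterministic footprint fixture: 100 rows, 17 with qc_flag 0."""
    rng = np.random.default_rng(42)
    n = 100
    flags = np.ones(n, dtype=int)
    flags[rng.choice(n, 17, replace=False)] = 0
    return pd.DataFrame(
        {
            "id": [f"fp{i:03d}" for i in range(n)],
            "date": pd.Timestamp(dt.date(2023, 6, 1)),
            "lat": rng.uniform(-1, 1, n),
            "lon": rng.uniform(0, 2, n),
            "sif_757": rng.uniform(0, 2, n),
            "sif_771": rng.uniform(0, 1.5, n),
            "qc_flag": flags,
        }
    )
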