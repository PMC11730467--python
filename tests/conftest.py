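import numpy as np
import pandas as pd
import pytest

from coashift import SimScenario, simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_scenario():
    """Fast scenario: few species, short banding set."""
    return SimScenario(n_species=6, seed=11, n_banding_records=1500)


@pytest.fixture
def tree20():
    return simulate_tree(20, seed=42)


@pytest.fixture
def stratum_frame():
    """Tiny valid stratum index table (3 rows, one species/season/year)."""
    return pd.DataFrame({
        "species": ["sp1"] * 3,
        "season": ["breeding"] * 3,
        "stratum_id": ["a", "b", "c"],
        "centroid_lon": [-100.0, -95.0, -90.0],
        "centroid_lat": [30.0, 40.0, 50.0],
        "year": [2000, 2000, 2000],
        "index_median": [1.0, 2.0, 3.0],
        "index_lo95": [0.8, 1.6, 2.4],
        "index_hi95": [1.2, 2.4, 3.6],
    })
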