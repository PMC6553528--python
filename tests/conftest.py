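import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import silacmap as sm

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_experiment():
    """A small simulated experiment shared across read-only tests."""
    config = sm.SimConfig(n_background=200, n_spiked=10, seed=42)
    observations, truth = sm.simulate_experiment(config)
    return config, observations, truth


@pytest.fixture(scope="session")
def table1():
    return sm.load_table1_fixture()


@pytest.fixture()
def protein_group_frame():
    """Hand-built protein-group records covering every provenance case."""
    return pd.DataFrame(
        {
            "protein_id": ["P1", "P2", "P3", "P4"],
            "gene_name": ["G1", "G2", "G3", "G4"],
            "replicate": [1, 1, 1, 1],
            "intensity_h": [8e5, 5e5, 6e6, 2e6],
            "intensity_l": [4e5, 4e5, 2e6, 0.0],
            "ratio_hl": [np.nan, np.nan, 3.1, np.nan],
            "ratio_count": [1, 1, 5, 0],
            "ratio_provenance": ["none", "none", "computed", "none"],
        }
    )
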