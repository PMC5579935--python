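import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mirstrat import synthetic_data as sd

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    return sd.SimulationConfig(
        n_species=12,
        n_mirnas=150,
        n_diseases=30,
        n_genes=400,
        family_count=12,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return sd.simulate_bundle(small_config)


def truth_age_table(truth: pd.DataFrame) -> pd.DataFrame:
    """Planted ages in the layout of the estimator's age table."""
    return pd.DataFrame(
        {
            "accession": truth["accession"],
            "group_id": truth["mirna"],
            "origin_node": truth["origin_node"],
            "age_my": truth["age_my"],
            "age_class": np.where(truth["age_my"] < 100.0, "young", "old"),
        }
    )


@pytest.fixture(scope="session")
def small_ages(small_bundle):
    return truth_age_table(small_bundle.characters.truth)


def random_tree(seed: int, n_species: int = None, depth: float = 500.0):
    """Random calibrated tree for oracle sweeps (2..16 leaves)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 17)) if n_species is None else n_species
    cfg = sd.SimulationConfig(n_species=n, tree_depth_my=depth, n_mirnas=1, seed=seed)
    return sd.simulate_tree(cfg, seed=seed).tree
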