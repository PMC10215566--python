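import numpy as np
import pandas as pd
import pytest

from csfmark.config import SimulationConfig, MissingModel
from csfmark.simulate import simulate_discovery_study
from csfmark.tmt import (
    log2_zscore,
    median_normalize,
    merge_batches,
    normalize_to_master_pool,
)


def discovery_labels(sheet: pd.DataFrame) -> pd.Series:
    disc = sheet[sheet["cohort_role"] == "discovery+validation"]
    return pd.Series(disc["group"].to_numpy(), index=disc["subject_id"].to_numpy())


def run_tmt_chain(batches, mode="intersection"):
    normalized = [normalize_to_master_pool(b) for b in batches]
    merged, counts = merge_batches(normalized, mode=mode, impute=True)
    return log2_zscore(median_normalize(merged)), counts


@pytest.fixture(scope="session")
def null_study():
    """All-null 100-protein 20v20 study without dropout."""
    config = SimulationConfig(
        n_proteins=100,
        missing_model=MissingModel(max_rate=0.0),
        seed=11,
    )
    batches, sheet, truth = simulate_discovery_study(config)
    matrix, _ = run_tmt_chain(batches)
    return matrix, discovery_labels(sheet), truth


@pytest.fixture(scope="session")
def effect_study():
    """Small study with one strong and one moderate true effect."""
    config = SimulationConfig(
        n_proteins=80,
        effect_table={"CHIT1": 3.99428, "SERPINA3": 1.077944},
        missing_model=MissingModel(max_rate=0.0),
        seed=5,
    )
    batches, sheet, truth = simulate_discovery_study(config)
    matrix, _ = run_tmt_chain(batches)
    return matrix, discovery_labels(sheet), truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
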