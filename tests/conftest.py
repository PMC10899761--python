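import numpy as np
import pandas as pd
import pytest

from trapquant import SimulationConfig, simulate_experiment
from trapquant.matrix import FeatureIntensityMatrix


@pytest.fixture(scope="session")
def small_sim():
    """One small, fully generated experiment shared across tests."""
    return simulate_experiment(SimulationConfig(n_proteins=80, seed=101))


@pytest.fixture(scope="session")
def noiseless_sim():
    """No noise, no missingness: pipeline output must equal the truth."""
    cfg = SimulationConfig(
        n_proteins=40,
        peptides_per_protein_min=2,
        peptides_per_protein_mean=3,
        replicate_sd_log2=0.0,
        channel_sd_log2=0.0,
        peptide_offset_sd_log2=0.5,
        mnar_midpoint_log2=-100.0,
        mcar_rate=0.0,
        dda_peptide_fraction=1.0,
        seed=5,
    )
    return simulate_experiment(cfg)


def make_fim(values: pd.DataFrame, scale: str = "log2") -> FeatureIntensityMatrix:
    feat = pd.DataFrame(
        {"gene": [f"g{i}" for i in range(len(values))], "protein_ids": ""},
        index=values.index,
    )
    return FeatureIntensityMatrix(values, feat, scale)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
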