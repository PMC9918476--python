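import numpy as np
import pandas as pd
import pytest

from sigspec.datasets import ExpressionDataset
from sigspec.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort, shared across tests (seed 0)."""
    return generate_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def clean_cohort():
    """Low-noise, high-effect cohort for recovery tests that state those conditions."""
    return generate_cohort(SimulationConfig(seed=7, delta=2.0, noise_sd=0.3))


@pytest.fixture()
def tiny_dataset():
    """3 genes x 4 samples log2 dataset with hand-set metadata."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [5.0, 5.0, 5.0, 5.0]],
        index=["G1", "G2", "G3"],
        columns=["S1", "S2", "S3", "S4"],
    )
    meta = pd.DataFrame(
        {
            "tissue_type": ["primary_tumor", "primary_tumor", "cell_line", "caf"],
            "purity": [0.5, 0.9, 1.0, np.nan],
            "histology_confirmed": [True, True, True, pd.NA],
        },
        index=pd.Index(["S1", "S2", "S3", "S4"], name="sample_id"),
    )
    return ExpressionDataset(values=values, scale="log2", metadata=meta, log2_pseudocount=1.0)
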