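import numpy as np
import pandas as pd
import pytest

from cartnet import AbundanceMatrix, SimConfig, quantify, simulate_dataset


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def noise_free_config() -> SimConfig:
    """All measurement-noise channels off; biology (block structure) kept."""
    return SimConfig(
        peptide_cv=0.0,
        sample_scale_sd=0.0,
        batch_log2_shift={"run1": 0.0, "run2": 0.0},
        peptide_response_factors={},  # empty mapping -> all factors 1.0
    )


@pytest.fixture(scope="session")
def dataset(default_config):
    return simulate_dataset(default_config, seed=7)


@pytest.fixture(scope="session")
def abundance(dataset):
    return quantify(dataset["peptide_table"], dataset["sample_sheet"])


def matrix_from_truth(truth) -> AbundanceMatrix:
    """Wrap a ground-truth matrix as an AbundanceMatrix (no measurement layer)."""
    samples = truth.samples.copy()
    if "run" not in samples.columns:
        samples["run"] = "run1"
    return AbundanceMatrix(values=truth.values, samples=samples)


def null_feature_matrix(n_features: int, n_per_group: int, seed: int,
                        groups=("A", "B", "C")) -> tuple[pd.DataFrame, pd.Series]:
    """iid lognormal feature table with no group effects, for null testing."""
    rng = np.random.default_rng(seed)
    cols = [f"{g}{i}" for g in groups for i in range(n_per_group)]
    values = pd.DataFrame(
        2.0 ** rng.normal(0, 1, (n_features, len(cols))),
        index=[f"f{i}" for i in range(n_features)],
        columns=cols,
    )
    labels = pd.Series([c[0] for c in cols], index=cols)
    return values, labels
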