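import numpy as np
import pandas as pd
import pytest

from uroprot.synthetic import CohortConfig, make_sample_table


@pytest.fixture
def small_samples() -> pd.DataFrame:
    return make_sample_table(4, 4)


@pytest.fixture
def small_matrix(small_samples) -> pd.DataFrame:
    """8 proteins x 8 samples, complete, with one planted 4x effect."""
    rng = np.random.default_rng(42)
    values = 2.0 ** rng.normal(20, 1, size=(8, 8))
    matrix = pd.DataFrame(
        values,
        index=[f"SP{i:05d}" for i in range(1, 9)],
        columns=small_samples["sample_id"].tolist(),
    )
    matrix.iloc[0, :4] *= 4.0  # upregulated in cases
    return matrix


@pytest.fixture
def null_config() -> CohortConfig:
    """No planted effects, no proteinuria, no missingness."""
    return CohortConfig(
        n_proteins=200,
        n_de_up=0,
        n_de_down=0,
        proteinuria_log2_mean=0.0,
        proteinuria_log2_sd=0.0,
        missing_midpoint_log2=-50.0,
        seed=11,
    )
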