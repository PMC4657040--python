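import numpy as np
import pytest

from relfdr.core_io import CovariateTable, ReplicateIntensityTensor
from relfdr.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def tiny_tensor() -> ReplicateIntensityTensor:
    """2 features x 2 samples x 3 replicates with known cells."""
    values = np.array(
        [
            [[2.0, 0.0, 4.0], [1.0, 1.0, 1.0]],
            [[5.0, 5.0, 5.0], [3.0, 0.0, 0.0]],
        ]
    )
    return ReplicateIntensityTensor(
        values=values, feature_ids=["f1", "f2"], sample_ids=["s1", "s2"]
    )


@pytest.fixture(scope="session")
def small_null_dataset():
    """A scaled-down null dataset shared by the slower statistical tests."""
    config = SimulationConfig(
        n_real=800, n_noise=400, n_de=0, signal=0.0, seed=20260924
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def small_signal_dataset():
    config = SimulationConfig(
        n_real=800, n_noise=400, n_de=80, signal=2.0, seed=20260925
    )
    return simulate_dataset(config)


@pytest.fixture
def gaussian_covariates() -> CovariateTable:
    import pandas as pd

    rng = np.random.default_rng(5)
    return CovariateTable(risk_factor=pd.Series(rng.standard_normal(40), name="risk"))
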