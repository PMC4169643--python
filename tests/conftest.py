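import numpy as np
import pytest

from htx.synthetic_cohort import (
    ChainSpec,
    FusionSpec,
    OutlierSpec,
    SimConfig,
    TdSpec,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down cohort for unit tests (full scale lives in acceptance)."""
    return SimConfig(
        n_samples=31,
        n_genes=300,
        outlier_spec=OutlierSpec(n_outlier_genes=30, n_carrier_samples=2),
        fusion_spec=FusionSpec(),
        chain_spec=ChainSpec(n_chains=2),
        td_spec=TdSpec(n_duplications=40, n_subclonal=2),
        seed=12345,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
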