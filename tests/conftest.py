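import numpy as np
import pandas as pd
import pytest

from healthineq import SyntheticConfig, generate_population


@pytest.fixture(scope="session")
def default_wave() -> pd.DataFrame:
    """A medium-sized synthetic wave under default study conditions."""
    return generate_population(SyntheticConfig(n=3000, seed=42))


@pytest.fixture(scope="session")
def blob_wave() -> pd.DataFrame:
    """A wave with two planted SES blobs 6 SD apart (n=400)."""
    return generate_population(
        SyntheticConfig(n=400, seed=11, cluster_separation=6.0)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
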