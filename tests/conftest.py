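import numpy as np
import pandas as pd
import pytest

from spongenet.profiles import table1_profiles


@pytest.fixture(scope="session")
def profiles():
    return table1_profiles()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_expression(rng) -> pd.DataFrame:
    """5 samples x 3 miRNAs, strictly positive, no special structure."""
    values = np.exp(rng.normal(size=(5, 3)))
    return pd.DataFrame(values, index=[f"s{i}" for i in range(5)], columns=["mA", "mB", "mC"])
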