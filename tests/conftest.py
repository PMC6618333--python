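import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from limi import VariableSpec
from limi.scenarios import gen_latent_matching

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def mixed_specs():
    """Continuous + 4-level categorical + binary, the canonical mixed layout."""
    return [
        VariableSpec("y", "continuous"),
        VariableSpec("x1", "categorical", n_levels=4),
        VariableSpec("x2", "binary"),
    ]


@pytest.fixture
def mixed_incomplete(rng):
    """Small mixed dataset with ~20% missing cells in every column."""
    df = gen_latent_matching(120, rng)
    out = df.copy()
    for col in out.columns:
        out.loc[rng.random(len(out)) < 0.2, col] = np.nan
    # keep at least a few observed values per column
    assert out.notna().sum().min() > 10
    return df, out
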