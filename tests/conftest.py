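"""Shared fixtures: small deterministic datasets with known truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from kranzsep import CountMatrix, SimConfig, simulate_activity_table

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def tiny_counts() -> CountMatrix:
    counts = pd.DataFrame(
        {"s1": [10, 10, 0], "s2": [20, 20, 5]},
        index=["gA", "gB", "gC"],
    )
    lengths = pd.Series([1000, 2000, 500], index=counts.index)
    return CountMatrix(counts=counts, lengths=lengths)


@pytest.fixture
def noiseless_activity() -> pd.DataFrame:
    """3 fractions x 4 replicates, two markers plus one alpha=0.75 analyte."""
    config = SimConfig(noise_sigma=0.0, seed=11)
    return simulate_activity_table(
        [("T75", 0.75, 1.0)], purities=(0.8, 0.5, 0.25), replicates=4, config=config
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
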