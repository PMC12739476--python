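import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")

from droughteval import (
    aggregate_to_samples,
    default_design,
    default_registry,
    generate,
)


@pytest.fixture
def registry():
    return default_registry()


@pytest.fixture
def toy_df():
    """1 genotype, 2 stages, 1 replicate, 2 indicators."""
    return pd.DataFrame(
        {
            "genotype": ["g"] * 4,
            "stage": ["control", "control", "T1", "T1"],
            "replicate": [1, 1, 1, 1],
            "indicator": ["Lth", "MDA", "Lth", "MDA"],
            "value": [0.45, 9.0, 0.42, 11.5],
        }
    )


@pytest.fixture(scope="session")
def synthetic_table():
    return generate(default_design(seed=1))


@pytest.fixture(scope="session")
def sample_matrix(synthetic_table):
    return aggregate_to_samples(synthetic_table)
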