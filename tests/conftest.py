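import numpy as np
import pytest

from callrep.features import build_feature_table
from callrep.synthetic import (
    SyntheticDatasetSpec,
    default_archetypes,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """15 calls/class x 5 well-separated archetypes, seed 42."""
    spec = SyntheticDatasetSpec(default_archetypes(), (15,) * 5, seed=42)
    recs, meta = generate_dataset(spec)
    return recs, meta


@pytest.fixture(scope="session")
def small_table(small_dataset):
    recs, _ = small_dataset
    return build_feature_table(recs)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
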