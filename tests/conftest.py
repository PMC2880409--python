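import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nabind.encoding import EncodingDescriptor, encode_dataset
from nabind.features import load_feature_table
from nabind.synthetic import SyntheticSpec, synth_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return load_feature_table()


@pytest.fixture(scope="session")
def small_dataset():
    """A cheap planted-signal dataset for unit tests."""
    return synth_dataset(
        SyntheticSpec(seed=11, n_sequences=10, length_range=(50, 70),
                      n_homologs=10)
    )


@pytest.fixture(scope="session")
def small_instances(small_dataset, table):
    profs = small_dataset.sequence_profiles(table)
    return encode_dataset(
        small_dataset.records, profs,
        EncodingDescriptor(groups=("hkm", "descriptors")),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
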