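import numpy as np
import pytest

from qheart.cohort import CohortSpec, encode_dataset, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default 918-record synthetic cohort, generated once per session."""
    spec = CohortSpec()
    return spec, generate_cohort(spec, seed=11)


@pytest.fixture(scope="session")
def encoded(default_cohort):
    spec, table = default_cohort
    return encode_dataset(table, spec, split_seed=11)


@pytest.fixture(scope="session")
def small_encoded():
    """A 120-record cohort for fast training smoke tests."""
    spec = CohortSpec(n_records=120)
    table = generate_cohort(spec, seed=5)
    return encode_dataset(table, spec, split_seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
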