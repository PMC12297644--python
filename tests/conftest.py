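import numpy as np
import pytest

from cardiovault.cohort import CohortSpec, generate_cohort, feature_matrix


@pytest.fixture(scope="session")
def separable_cohort():
    """Well-separated 400-patient cohort with its generating spec."""
    spec = CohortSpec(n=400, effect_scale=2.0, seed=11)
    records = generate_cohort(spec)
    X, y = feature_matrix(records)
    return spec, records, X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
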