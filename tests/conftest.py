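import warnings

import numpy as np
import pytest

from ccnet.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete cohort shared by structural/pipeline tests."""
    spec = CohortSpec(n_ft=30, n_vpt=24, n_nodes=24, seed=101)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
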