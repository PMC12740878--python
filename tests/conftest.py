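import numpy as np
import pytest
from hypothesis import settings

from gsdecomp.synth import CohortSpec, gen_subject

# deterministic hypothesis runs
settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale cohort for fast unit tests."""
    return CohortSpec(
        n_subjects=4, n_rois=12, n_networks=3, n_volumes=120, seed=13
    )


@pytest.fixture(scope="session")
def default_subject():
    """One subject under the default study conditions (no raw physio)."""
    return gen_subject(CohortSpec(seed=5), 0, raw_physio=False)


@pytest.fixture(scope="session")
def small_subject(small_spec):
    return gen_subject(small_spec, 0, raw_physio=False)
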