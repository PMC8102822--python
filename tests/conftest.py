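import numpy as np
import pytest

from depfuse.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small strong-effect cohort shared across tests (8 subjects, 120 sessions)."""
    spec = CohortSpec.tiny(effect_size=2.0, seed=7)
    sessions, manifest = generate_cohort(spec)
    return spec, sessions, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
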