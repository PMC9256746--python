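import numpy as np
import pytest

from twinmorph import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """400 subjects with 40 MZ and 80 DZ pairs; reused read-only."""
    cfg = CohortConfig(n_subjects=400, n_mz_pairs=40, n_dz_pairs=80, seed=11)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
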