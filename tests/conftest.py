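import numpy as np
import pytest
from hypothesis import settings

from specfuse.blocks import FTIR, RAMAN
from specfuse.preprocessing import preprocess_block
from specfuse.synthetic import CohortSpec, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """Full-design cohort: 36 subjects, 25/10 replicates, default effects."""
    return generate_cohort(CohortSpec(seed=42))


@pytest.fixture(scope="session")
def default_blocks(default_cohort):
    """Preprocessed modality blocks plus the binary response."""
    blocks = {
        RAMAN: preprocess_block(default_cohort.raman_replicates, RAMAN),
        FTIR: preprocess_block(default_cohort.ftir_replicates, FTIR),
    }
    return blocks, default_cohort.label_vector()


@pytest.fixture(scope="session")
def small_cohort_spec():
    """Small cohort for I/O and CLI tests: coarse grids, few replicates."""
    spec = CohortSpec(n_per_class=6,
                      raman_grid=np.linspace(610.0, 1720.0, 60),
                      ftir_grid=np.linspace(400.0, 4000.0, 90),
                      n_replicates_raman=4, n_replicates_ftir=3, seed=5)
    return spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
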