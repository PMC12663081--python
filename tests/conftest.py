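import numpy as np
import pytest

from dynhub.pipeline import PipelineConfig
from dynhub.synthetic import SyntheticCohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (8 subjects, 12 nodes, 100 volumes) for fast
    end-to-end tests; the planted structure is the same as at full size."""
    spec = SyntheticCohortSpec(
        n_subjects=8, n_nodes=12, n_volumes=100, hub_index=3, seed=7
    )
    series, truth = simulate_cohort(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def small_config():
    return PipelineConfig(n_perm=200, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
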