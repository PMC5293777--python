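import numpy as np
import pytest

from axoquant.pipeline_io import CohortManifest, RunConfig, simulate_cohort
from axoquant.synthetic_data import SyntheticSpec


@pytest.fixture
def spec():
    """Default small spec; override fields via dataclasses.replace."""
    return SyntheticSpec(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory) -> tuple[CohortManifest, RunConfig]:
    """One shared n=2/group cohort for the pipeline-level tests."""
    root = tmp_path_factory.mktemp("cohort")
    config = RunConfig(seed=1, n_per_group=2)
    manifest = simulate_cohort(config, root)
    return manifest, config
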