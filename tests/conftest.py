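import warnings

import numpy as np
import pytest

from brainprint import pipeline, synth

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_config() -> synth.CohortConfig:
    """2 twin pairs x 2 weeks x 3 tasks — enough structure for unit tests."""
    return synth.CohortConfig(
        n_pairs=2, weeks=2, tasks=("rce", "roe", "mbi"), seed=5
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    recs, gt = synth.generate_cohort(small_config)
    return recs, gt


@pytest.fixture(scope="session")
def small_features(small_config):
    """Concatenated-mode features of the small cohort (no ICA, for speed)."""
    fs, _ = pipeline.cohort_features(
        small_config, use_ica=False, qc=False
    )
    return fs


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
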