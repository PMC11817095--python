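import numpy as np
import pytest

from dentage.synthetic_cohort import CohortConfig, generate_cohort, write_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient synthetic cohort shared across unit tests."""
    cfg = CohortConfig(n_patients=60, image_height=32, image_width=32, rng_seed=11)
    records, images = generate_cohort(cfg)
    return cfg, records, images


@pytest.fixture(scope="session")
def small_manifest(small_cohort, tmp_path_factory):
    """The small cohort written to disk; returns (config, manifest path)."""
    cfg, records, images = small_cohort
    out = tmp_path_factory.mktemp("cohort60")
    return cfg, write_cohort(records, images, out)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
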