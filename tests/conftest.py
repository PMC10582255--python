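from dataclasses import replace

import numpy as np
import pytest

from mgmv.synthetic import SiteSpec, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size default cohort (120 HC / 88 PD, 40 ROIs, 3 sites)."""
    return generate_cohort(SyntheticConfig(), seed=2024)


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast unit tests: 60 HC / 20 PD, 8 ROIs, 1 site."""
    return replace(
        SyntheticConfig(), n_hc=60, n_pd=20, n_roi=8,
        sites=(SiteSpec("solo", 1.0, 0.0, 1.0),))


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
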