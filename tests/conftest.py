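import numpy as np
import pytest

from netcollapse.synth import (SyntheticConfig, make_cohort,
                               make_structure_function_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Oscillator-driven cohort small enough for per-test reuse."""
    cfg = SyntheticConfig(n_subjects=12, n_regions=24, n_timepoints=240, seed=3)
    return make_cohort(cfg)


@pytest.fixture(scope="session")
def sf_cohort():
    """Planted low-rank structure-function cohort (120 subjects, 40 regions)."""
    return make_structure_function_cohort(n_subjects=120, n_regions=40,
                                          n_components=3, coupling_r=0.6,
                                          seed=5)
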