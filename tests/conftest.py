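import numpy as np
import pandas as pd
import pytest

from mcrstress.cli_io import analyse_cohort
from mcrstress.synthetic_cohort import Cohort, GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """One default-configuration cohort, shared across tests."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def analysed(default_cohort):
    """Full pipeline output for the shared default cohort."""
    return analyse_cohort(default_cohort.subjects, default_cohort.trials,
                          mri=default_cohort.mri, seed=1)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """A small cohort for cheap structural checks."""
    cfg = GeneratorConfig(n_healthy=10, n_diagnosed=6, seed=11)
    return generate_cohort(cfg)
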