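import numpy as np
import pytest

from grex import (ExposureProfile, SimulationConfig, default_panel,
                  generate_cohort)


@pytest.fixture(scope="session")
def panel26():
    return default_panel("FEV1_FVC")


@pytest.fixture(scope="session")
def profile():
    return ExposureProfile()


@pytest.fixture(scope="session")
def small_cohort():
    """A 4,000-sample cohort with a planted common interaction effect."""
    config = SimulationConfig(n=4_000, seed=11, study_id="fixture")
    return generate_cohort(config), config


@pytest.fixture()
def rng():
    return np.random.default_rng(2023)
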