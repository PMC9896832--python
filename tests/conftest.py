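import numpy as np
import pytest

from oksmap.simulate import CohortSpec, default_study_spec, generate_cohort


@pytest.fixture(scope="session")
def estimation_cohort():
    return generate_cohort(default_study_spec("estimation"))


@pytest.fixture(scope="session")
def validation_cohort():
    return generate_cohort(default_study_spec("validation"))


@pytest.fixture(scope="session")
def big_cohort():
    """A large draw from the calibrated population for Monte-Carlo checks."""
    return generate_cohort(CohortSpec(n_patients=5000, seed=7))


@pytest.fixture(scope="session")
def toy_value_sets():
    from oksmap.instruments import bundled_value_sets

    return bundled_value_sets()
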