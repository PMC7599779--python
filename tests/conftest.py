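import numpy as np
import pytest

from uadese import anova, fit_quadratic, reduce_model
from uadese.pipeline import default_factors, load_bundled_design


@pytest.fixture(scope="session")
def study_table():
    """The bundled 29-run Box-Behnken design with measured yields."""
    return load_bundled_design()


@pytest.fixture(scope="session")
def factors():
    return default_factors()


@pytest.fixture(scope="session")
def full_model(study_table):
    return fit_quadratic(study_table)


@pytest.fixture(scope="session")
def study_anova(full_model, study_table):
    return anova(full_model, study_table)


@pytest.fixture(scope="session")
def reduced_model(full_model, study_anova, study_table):
    return reduce_model(full_model, study_anova, study_table, alpha=0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
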