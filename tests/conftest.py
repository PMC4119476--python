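import numpy as np
import pytest

from maxed.marginals import FamilyMarginals, two_dose_hypotheses
from maxed.priors import IMPriorSpec

# Fixed suite seed: the motivating study's publication date.
SUITE_SEED = 20140729


@pytest.fixture(scope="session")
def suite_seed() -> int:
    return SUITE_SEED


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture(scope="session")
def spec_tau1() -> IMPriorSpec:
    """The study's efficacy prior: null 0.1, mode at the 0.3 target."""
    return IMPriorSpec(null_value=0.1, tau=0.06)


@pytest.fixture(scope="session")
def spec_tau2() -> IMPriorSpec:
    """The study's between-dose difference prior: null 0, mode at 0.1."""
    return IMPriorSpec(null_value=0.0, tau=0.015)


@pytest.fixture(scope="session")
def two_dose_family():
    return two_dose_hypotheses(theta0=0.1, tau1=0.06, tau2=0.015)


@pytest.fixture(scope="session")
def family_marginals(two_dose_family) -> FamilyMarginals:
    return FamilyMarginals(two_dose_family)
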