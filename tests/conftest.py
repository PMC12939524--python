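import numpy as np
import pytest

from pjibench.cohort import CohortSpec, default_rater_profiles, generate_cohort
from pjibench.score import fit_surrogate


@pytest.fixture(scope="session")
def study_cohort():
    """A 274-case cohort at the study prevalence (42 PJI / 232 aseptic)."""
    return generate_cohort(CohortSpec(n_cases=274, prevalence=0.153, rng_seed=1))


@pytest.fixture(scope="session")
def training_cohort():
    return generate_cohort(CohortSpec(n_cases=2000, prevalence=0.153, rng_seed=7))


@pytest.fixture(scope="session")
def default_model(training_cohort):
    return fit_surrogate(training_cohort, seed=7)


@pytest.fixture(scope="session")
def rater_profiles(study_cohort):
    """Published-table physician profiles, with the non-inconclusive Stage-I
    rate back-solved from the cohort's realized inconclusive fraction."""
    frac = np.mean([v.icm_class == "inconclusive" for v in study_cohort])
    return default_rater_profiles(inconclusive_fraction=float(frac))
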