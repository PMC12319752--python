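import warnings

import pytest
from hypothesis import HealthCheck, settings

from brainnorm.gamlss_engine import FitConfig, fit_normative
from brainnorm.synthetic_cohorts import SimConfig, simulate_cohort
from brainnorm.validation import TARGET, log_cohort

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_cohort():
    """One mid-size multi-site control cohort shared across tests."""
    cohort, truth = simulate_cohort(SimConfig(
        n_subjects=1500, n_sites=5, regions=("precentral",),
        metrics=("thickness_mm",), include_folding=False, seed=42))
    return log_cohort(cohort), truth


@pytest.fixture(scope="session")
def fitted(sim_cohort):
    """A converged normative fit on the shared cohort."""
    cohort, truth = sim_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = fit_normative(cohort, TARGET, FitConfig())
    assert res.converged
    return res, cohort, truth
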