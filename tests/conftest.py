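"""Shared fixtures: a simulated linked study cohort, fitted sex-specific
algorithms, an unlinked application survey and an observed-rate table.

Session-scoped because Cox fits dominate suite runtime; tests must not
mutate fixture frames in place (copy first).
"""

import warnings

import numpy as np
import pytest

from lifeburden import exposures, hazard, riskengine, synthetic


@pytest.fixture(scope="session")
def study_config():
    return synthetic.CohortConfig(n=20_000, seed=0)


@pytest.fixture(scope="session")
def linked_cohort(study_config):
    cohort = synthetic.generate_cohort(study_config)
    return synthetic.simulate_followup(cohort, study_config)


@pytest.fixture(scope="session")
def coded_linked(linked_cohort):
    coded, dropped = exposures.code_survey(linked_cohort)
    assert len(dropped) == 0
    return coded


@pytest.fixture(scope="session")
def fitted_models(coded_linked):
    return {
        sex: hazard.fit_ph(coded_linked, hazard.ModelSpec(sex=sex))
        for sex in ("male", "female")
    }


@pytest.fixture(scope="session")
def algorithms(fitted_models):
    return {sex: hazard.extract_algorithm(m) for sex, m in fitted_models.items()}


@pytest.fixture(scope="session")
def application_survey(study_config):
    return synthetic.generate_cohort(study_config, n=8_000, seed=7)


@pytest.fixture(scope="session")
def coded_survey(application_survey):
    coded, dropped = exposures.code_survey(application_survey)
    assert len(dropped) == 0
    return coded


@pytest.fixture(scope="session")
def observed_rates(study_config):
    return synthetic.observed_rate_table(study_config, seed=13)


@pytest.fixture(scope="session")
def calibrated_algorithms(algorithms, coded_survey, observed_rates):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            sex: riskengine.recalibrate(alg, coded_survey, observed_rates)
            for sex, alg in algorithms.items()
        }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
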