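import numpy as np
import pandas as pd
import pytest

from acsmarkov.cohort_measures import EligibilityWindow, build_covariates, select_eligible
from acsmarkov.markov_model import TransitionProbabilities
from acsmarkov.synthetic_data import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def fig2_probs() -> TransitionProbabilities:
    """The published point estimates and 95% intervals for each transition."""
    return TransitionProbabilities(
        p_referral=(0.04, 0.02, 0.06),
        p_engage_given_referral=(0.47, 0.37, 0.57),
        p_engage_given_no_referral=(0.20, 0.16, 0.24),
        p_drug_death_given_engaged=(0.03, 0.00, 0.07),
        p_drug_death_given_not_engaged=(0.06, 0.02, 0.10),
        p_nondrug_death_given_engaged=(0.07, 0.01, 0.13),
        p_nondrug_death_given_not_engaged=(0.09, 0.05, 0.13),
    )


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(n_patients=4000, seed=20240401)


@pytest.fixture(scope="session")
def cohort(sim_config):
    return generate_cohort(sim_config)


@pytest.fixture(scope="session")
def large_analysis_table() -> pd.DataFrame:
    """A larger cohort for asymptotic checks (posterior mean vs MLE)."""
    big = generate_cohort(SimConfig(n_patients=12_000, seed=20240402))
    eligible = select_eligible(big.admissions, EligibilityWindow(), patients=big.patients)
    table = build_covariates(
        eligible, big.admissions, big.fills, big.deaths,
        patients=big.patients, referrals=big.truth,
    )
    table["drug_death"] = (table["death_category"] == "drug").astype(int)
    table["nondrug_death"] = (table["death_category"] == "non_drug").astype(int)
    return table


@pytest.fixture(scope="session")
def analysis_table(cohort) -> pd.DataFrame:
    eligible = select_eligible(
        cohort.admissions, EligibilityWindow(), patients=cohort.patients
    )
    table = build_covariates(
        eligible,
        cohort.admissions,
        cohort.fills,
        cohort.deaths,
        patients=cohort.patients,
        referrals=cohort.truth,
    )
    table["drug_death"] = (table["death_category"] == "drug").astype(int)
    table["nondrug_death"] = (table["death_category"] == "non_drug").astype(int)
    return table
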