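"""Shared fixtures: one study-sized cohort and one large cohort per session."""

import numpy as np
import pandas as pd
import pytest

import rtmicrocost as rtm

STUDY_SEED = 7
LARGE_SEED = 11


@pytest.fixture(scope="session")
def unit_costs():
    return rtm.default_unit_costs()


@pytest.fixture(scope="session")
def study_cohort():
    """Cohort at the study conditions (106 VMAT / 49 HT), fixed seed."""
    config = rtm.default_cohort_config(seed=STUDY_SEED)
    patients, events, toxicity = rtm.generate_cohort(config)
    return config, patients, events, toxicity


@pytest.fixture(scope="session")
def study_breakdowns(study_cohort, unit_costs):
    _, patients, events, _ = study_cohort
    arms = patients.set_index("patient_id")["arm"]
    return rtm.cost_breakdowns(events, arms, unit_costs)


@pytest.fixture(scope="session")
def study_weights(study_cohort):
    _, patients, _, _ = study_cohort
    results = rtm.PropensityModel(patients).fit()
    return pd.Series(results.stabilized_weights, index=patients["patient_id"].to_numpy())


@pytest.fixture(scope="session")
def large_patients():
    """20,000 patients at the study's 106:49 arm ratio, covariates only."""
    config = rtm.default_cohort_config(n_vmat=13677, n_ht=6323, seed=LARGE_SEED)
    return rtm.generate_patients(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
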