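import numpy as np
import pandas as pd
import pytest

import workstates as ws


@pytest.fixture(scope="session")
def small_cohort() -> ws.SyntheticCohort:
    """A modest synthetic register cohort shared across test modules."""
    return ws.generate_cohort(ws.GeneratorConfig(n_persons=2000, seed=11))


@pytest.fixture(scope="session")
def small_states(small_cohort) -> pd.DataFrame:
    return ws.classify_cohort(small_cohort.records, ws.ClassificationConfig())


@pytest.fixture(scope="session")
def small_panel(small_cohort, small_states) -> pd.DataFrame:
    rec = small_cohort.records
    pm = ws.PeriodMap()
    ids = ws.select_baseline(small_states, pm.baseline_year)
    covariates = rec[
        ["person_id", "year", "sex", "birth_year", "country_of_birth", "education"]
    ]
    inpatient = rec[["person_id", "year", "inpatient_days_countable"]].rename(
        columns={"inpatient_days_countable": "days"}
    )
    panel, _ = ws.build_person_periods(
        small_states[small_states["person_id"].isin(ids)], covariates, inpatient, pm
    )
    return panel


@pytest.fixture(scope="session")
def kernel_panel() -> pd.DataFrame:
    """Panel simulated straight from the published-OR kernel (known truth)."""
    truth = ws.coefficients_from_printed_ors()
    cov = ws.sample_covariate_table(4000, seed=21)
    states = ws.simulate_trajectories(truth, cov, periods=5, seed=22)
    return ws.trajectories_to_panel(states, cov)
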