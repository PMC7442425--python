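import numpy as np
import pandas as pd
import pytest

import pharmsignal as ps

# Study conditions for the confounded-cohort scenario used across tests:
# treatment choice loaded on sex and comorbidity, outcome hazard loaded on
# the same comorbidities, so the crude HR is biased and the propensity
# model has real work to do.
TREATMENT_COEFS = {"female": 0.8, "diabetes": -0.5, "heart_disease": 0.6}
OUTCOME_COV_EFFECTS = {"heart_disease": 0.7, "diabetes": 0.4}


def confounded_config(n_persons, seed, true_hr=2.0, n_negative_controls=0, nc_bias=0.0):
    outcomes = (
        ps.OutcomeSpec(
            "sae",
            baseline_hazard=0.001,
            log_hr_target=float(np.log(true_hr)),
            covariate_log_hr=dict(OUTCOME_COV_EFFECTS),
        ),
    )
    if n_negative_controls:
        outcomes = outcomes + ps.negative_control_specs(
            n_negative_controls, baseline_hazard=0.002, confounder_log_hr=nc_bias
        )
    confounder = ps.UnmeasuredConfounder(prevalence=0.3, treatment_log_odds=1.5 if nc_bias else 0.0)
    return ps.SimConfig(
        n_persons=n_persons,
        seed=seed,
        treatment_coefs=dict(TREATMENT_COEFS),
        outcomes=outcomes,
        confounder=confounder,
    )


@pytest.fixture(scope="session")
def confounded_db():
    """One moderately sized confounded database shared by read-only tests."""
    return ps.simulate(confounded_config(n_persons=8000, seed=42))


@pytest.fixture(scope="session")
def cohort_and_strata(confounded_db):
    db = confounded_db
    eras = ps.build_drug_eras(db.drug_exposures)
    cohort = ps.select_new_users(db, "target_drug", "comparator_drug", "indication", eras=eras)
    model = ps.fit_propensity_model(cohort[list(db.covariates.columns)], cohort["arm"], seed=7)
    strata = ps.stratify_by_quintile(model.scores.to_numpy())
    return db, eras, cohort, model, strata


def tiny_database(persons, observation_periods, drug_exposures, condition_occurrences,
                  covariates=None, start_year=2010):
    """Hand-built SimulatedDatabase for fixture tests."""
    pid = persons["person_id"]
    cov = covariates if covariates is not None else pd.DataFrame(index=pd.Index(pid, name="person_id"))
    first = drug_exposures.sort_values("start_day").drop_duplicates("person_id")
    index_day = first.set_index("person_id")["start_day"].reindex(pid.values)
    return ps.SimulatedDatabase(
        persons=persons,
        observation_periods=observation_periods,
        drug_exposures=drug_exposures,
        condition_occurrences=condition_occurrences,
        covariates=cov,
        index_day=index_day,
        confounder=pd.Series(0, index=pid.values),
        truth={"config": {"target_code": "target_drug", "comparator_code": "comparator_drug",
                          "indication_code": "indication", "start_year": start_year}},
    )
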