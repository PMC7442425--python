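"""End-to-end estimation driver for one database.

Chains the stages in study order: drug eras -> new-user cohort ->
propensity model and quintile strata -> covariate-balance gate -> per-
outcome risk intervals and stratified Cox fits -> empirical null from the
negative-control estimates -> calibrated results.  Analyses failing the
balance gate or with zero events in an arm are carried through as exclusion
records so that reports can show *why* a cell is empty.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calibration, cohorts, outcome, propensity
from .synthetic import SimulatedDatabase

__all__ = ["DatabaseResults", "run_cohort_analysis", "results_table"]


@dataclass
class DatabaseResults:
    """All per-outcome estimates for one database and one time-at-risk."""

    cohort: pd.DataFrame
    model: propensity.PropensityModel
    strata: np.ndarray
    balance: propensity.BalanceReport
    estimates: dict[str, outcome.EstimationResult]
    null: calibration.NullDistribution | None
    calibrated: dict[str, dict]


def run_cohort_analysis(
    db: SimulatedDatabase,
    outcome_codes: list[str],
    negative_control_codes: list[str],
    tar_spec: cohorts.TimeAtRiskSpec | None = None,
    target_code: str | None = None,
    comparator_code: str | None = None,
    indication_code: str | None = None,
    seed: int = 0,
    ps_folds: int = 10,
) -> DatabaseResults:
    """Run the full comparative-cohort pipeline on one simulated database."""
    cfg = db.truth["config"]
    target_code = target_code or cfg["target_code"]
    comparator_code = comparator_code or cfg["comparator_code"]
    indication_code = indication_code or cfg["indication_code"]
    tar_spec = tar_spec or cohorts.TimeAtRiskSpec()

    eras = cohorts.build_drug_eras(db.drug_exposures, max_gap_days=tar_spec.era_gap_days)
    cohort = cohorts.select_new_users(db, target_code, comparator_code, indication_code, eras=eras)
    cov_cols = list(db.covariates.columns)
    X = cohort[cov_cols]
    model = propensity.fit_propensity_model(X, cohort["arm"], folds=ps_folds, seed=seed)
    strata = propensity.stratify_by_quintile(model.scores.to_numpy())
    balance = propensity.balance_report(X, cohort["arm"], strata)

    estimates: dict[str, outcome.EstimationResult] = {}
    all_codes = list(outcome_codes) + list(negative_control_codes)
    occ = db.condition_occurrences
    for code in all_codes:
        if not balance.passed:
            estimates[code] = outcome.EstimationResult.exclusion(
                code, f"covariate imbalance after stratification (max |SMD| = {balance.max_abs_smd_after:.3f})"
            )
            continue
        events = occ[occ["condition_code"] == code]
        intervals = cohorts.compute_time_at_risk(
            cohort, eras, events, tar_spec, db.observation_periods
        )
        # strata were assigned on the cohort; align to surviving intervals
        stratum_of = pd.Series(strata, index=cohort["person_id"].to_numpy())
        estimates[code] = outcome.fit_stratified_cox(
            intervals, stratum_of.loc[intervals["person_id"]].to_numpy(), analysis_id=code
        )

    nc_pairs = [
        (estimates[c].log_hr, estimates[c].se_log_hr)
        for c in negative_control_codes
        if not estimates[c].excluded
    ]
    null = calibration.fit_empirical_null(nc_pairs) if len(nc_pairs) >= 5 else None

    calibrated: dict[str, dict] = {}
    if null is not None:
        for code in outcome_codes:
            est = estimates[code]
            if not est.excluded:
                calibrated[code] = calibration.calibrate_estimate(est.log_hr, est.se_log_hr, null)
    return DatabaseResults(
        cohort=cohort,
        model=model,
        strata=strata,
        balance=balance,
        estimates=estimates,
        null=null,
        calibrated=calibrated,
    )


def results_table(results: DatabaseResults) -> pd.DataFrame:
    """Flatten a DatabaseResults into one row per analyzed outcome."""
    rows = []
    for code, est in results.estimates.items():
        row = dataclasses.asdict(est)
        row["outcome"] = code
        cal = results.calibrated.get(code)
        if cal:
            row.update(cal)
        rows.append(row)
    df = pd.DataFrame(rows)
    front = ["outcome", "hr", "ci95_low", "ci95_high"]
    return df[[c for c in front if c in df.columns] + [c for c in df.columns if c not in front]]
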