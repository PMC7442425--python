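"""Synthetic longitudinal claims data with known ground truth.

Emulates the statistical structure of administrative claims / EHR sources
mapped to a minimal OMOP-like schema: a persons table, one observation
period per person, era-fragmented drug dispensings, and condition
occurrences.  Treatment assignment is confounded by baseline covariates
through a logistic model; outcomes are drawn from exponential hazards with
configurable true hazard ratios; negative-control outcomes carry a true
hazard ratio of exactly 1 for the study drugs, optionally distorted by a
shared *unmeasured* confounder so that downstream empirical calibration has
real systematic error to estimate.

Time is integer days.  Day 0 is every person's observation start, anchored
at Jan 1 of ``start_year`` (365-day calendar years) so that ages and seasons
are well defined.  Only the first occurrence of each outcome per person is
recorded; recurrent-event histories for self-controlled designs come from
:func:`simulate_sccs_cases`.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "CovariateSpec",
    "OutcomeSpec",
    "ExposureSpec",
    "ObservationSpec",
    "UnmeasuredConfounder",
    "SimConfig",
    "SimulatedDatabase",
    "generate_population",
    "assign_treatments",
    "generate_outcomes",
    "simulate",
    "simulate_sccs_cases",
    "negative_control_specs",
    "write_database",
    "read_database",
]

# Independent RNG streams per generation stage, so adding outcomes never
# perturbs the population or treatment draws.
_STREAM_POPULATION = 0
_STREAM_TREATMENT = 1
_STREAM_OUTCOMES = 2
_STREAM_SCCS = 3


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class CovariateSpec:
    """A binary baseline covariate with a marginal prevalence."""

    name: str
    prevalence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError(
                f"prevalence of {self.name!r} must be in [0,1], got {self.prevalence}"
            )


@dataclass(frozen=True)
class OutcomeSpec:
    """One outcome's data-generating model.

    ``baseline_hazard`` is the daily event hazard for a person with all
    covariates zero in the comparator arm.  ``log_hr_target`` is the true
    log hazard ratio of the target drug versus the comparator.  Negative
    controls must have ``log_hr_target == 0``; ``confounder_log_hr`` routes
    the shared unmeasured confounder into the outcome hazard, which is what
    creates genuine systematic error for calibration to remove.
    """

    code: str
    baseline_hazard: float
    log_hr_target: float = 0.0
    covariate_log_hr: dict[str, float] = field(default_factory=dict)
    is_negative_control: bool = False
    confounder_log_hr: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ConfigError(
                f"baseline hazard of {self.code!r} must be > 0, got {self.baseline_hazard}"
            )
        if self.is_negative_control and self.log_hr_target != 0.0:
            raise ConfigError(
                f"negative control {self.code!r} must have log_hr_target = 0"
            )


@dataclass(frozen=True)
class ExposureSpec:
    """Dispensing pattern: initial fill plus refills separated by gaps.

    With ``fixed=True`` the means are used as exact values (handy for
    fixtures); otherwise refill counts and gaps are Poisson draws around the
    means.
    """

    days_supplied: int = 30
    n_refills_mean: float = 3.0
    refill_gap_mean: float = 10.0
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.days_supplied < 1:
            raise ConfigError("days_supplied must be >= 1")
        if self.n_refills_mean < 0 or self.refill_gap_mean < 0:
            raise ConfigError("refill parameters must be non-negative")


@dataclass(frozen=True)
class ObservationSpec:
    """Uniform integer ranges for observed days before / after the index."""

    days_before_index: tuple[int, int] = (400, 1500)
    days_after_index: tuple[int, int] = (90, 1095)

    def __post_init__(self) -> None:
        for lo, hi in (self.days_before_index, self.days_after_index):
            if lo < 0 or hi < lo:
                raise ConfigError("observation day ranges must satisfy 0 <= lo <= hi")


@dataclass(frozen=True)
class UnmeasuredConfounder:
    """A latent binary factor shared by treatment choice and outcomes.

    It is never exposed in the covariate table, so the propensity model
    cannot adjust for it; negative-control outcomes that load on it acquire
    biased crude estimates, which is the systematic error the calibration
    stage is built to absorb.
    """

    prevalence: float = 0.3
    treatment_log_odds: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError("confounder prevalence must be in [0,1]")


@dataclass(frozen=True)
class SimConfig:
    n_persons: int
    seed: int
    covariates: tuple[CovariateSpec, ...] = (
        CovariateSpec("female", 0.78),
        CovariateSpec("diabetes", 0.13),
        CovariateSpec("heart_disease", 0.15),
        CovariateSpec("hyperlipidaemia", 0.31),
        CovariateSpec("depression", 0.13),
        CovariateSpec("copd", 0.04),
    )
    treatment_intercept: float = 0.0
    treatment_coefs: dict[str, float] = field(default_factory=dict)
    outcomes: tuple[OutcomeSpec, ...] = ()
    exposure: ExposureSpec = ExposureSpec()
    observation: ObservationSpec = ObservationSpec()
    confounder: UnmeasuredConfounder = UnmeasuredConfounder()
    target_code: str = "target_drug"
    comparator_code: str = "comparator_drug"
    indication_code: str = "indication"
    indication_prevalence: float = 1.0
    age_range: tuple[int, int] = (18, 85)
    start_year: int = 2010

    def __post_init__(self) -> None:
        if self.n_persons <= 0:
            raise ConfigError(f"n_persons must be > 0, got {self.n_persons}")
        if not 0.0 <= self.indication_prevalence <= 1.0:
            raise ConfigError("indication_prevalence must be in [0,1]")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate covariate names")
        codes = [o.code for o in self.outcomes]
        if len(set(codes)) != len(codes):
            raise ConfigError("duplicate outcome codes")
        unknown = set(self.treatment_coefs) - set(names)
        if unknown:
            raise ConfigError(f"treatment coefficients reference unknown covariates: {sorted(unknown)}")


@dataclass
class SimulatedDatabase:
    """The four longitudinal tables plus ground truth.

    ``covariates`` is a wide person-by-covariate 0/1 table (the analysis-ready
    view of the baseline condition occurrences); ``confounder`` holds the
    latent factor that downstream code must never see.  ``truth`` records the
    config and realized per-outcome true hazard ratios.
    """

    persons: pd.DataFrame
    observation_periods: pd.DataFrame
    drug_exposures: pd.DataFrame
    condition_occurrences: pd.DataFrame
    covariates: pd.DataFrame
    index_day: pd.Series
    confounder: pd.Series
    truth: dict

    @property
    def arms(self) -> pd.Series:
        """0/1 target-arm indicator, derived from first dispensings."""
        first = (
            self.drug_exposures.sort_values("start_day")
            .drop_duplicates("person_id")
            .set_index("person_id")["drug_code"]
        )
        target = self.truth["config"]["target_code"]
        return (first == target).astype(int).reindex(self.persons["person_id"]).fillna(0).astype(int)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def generate_population(config: SimConfig) -> SimulatedDatabase:
    """Draw persons, observation periods and baseline condition occurrences."""
    rng = _rng(config, _STREAM_POPULATION)
    n = config.n_persons
    pid = np.arange(1, n + 1)

    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    yob = config.start_year - ages

    cov = {}
    for spec in config.covariates:
        cov[spec.name] = rng.binomial(1, spec.prevalence, size=n)
    covariates = pd.DataFrame(cov, index=pd.Index(pid, name="person_id")).astype(np.int8)

    sex = np.where(covariates["female"], "F", "M") if "female" in covariates else np.full(n, "F")
    persons = pd.DataFrame({"person_id": pid, "year_of_birth": yob, "sex": sex})

    lo_b, hi_b = config.observation.days_before_index
    lo_a, hi_a = config.observation.days_after_index
    before = rng.integers(lo_b, hi_b + 1, size=n)
    after = rng.integers(lo_a, hi_a + 1, size=n)
    observation_periods = pd.DataFrame(
        {"person_id": pid, "start_day": np.zeros(n, dtype=int), "end_day": before + after}
    )
    index_day = pd.Series(before, index=covariates.index, name="index_day")

    u = rng.binomial(1, config.confounder.prevalence, size=n)
    confounder = pd.Series(u, index=covariates.index, name="confounder")

    rows = []
    has_ind = rng.random(n) < config.indication_prevalence
    for p, flag in zip(pid, has_ind):
        if flag:
            rows.append((p, config.indication_code, 0))
    for name in covariates.columns:
        present = covariates[name].to_numpy().astype(bool)
        for p in pid[present]:
            rows.append((p, name, 0))
    condition_occurrences = pd.DataFrame(
        rows, columns=["person_id", "condition_code", "day"]
    ).sort_values(["person_id", "day"], kind="stable", ignore_index=True)

    truth = {
        "config": _config_to_dict(config),
        "true_hr": {o.code: math.exp(o.log_hr_target) for o in config.outcomes},
    }
    return SimulatedDatabase(
        persons=persons,
        observation_periods=observation_periods,
        drug_exposures=pd.DataFrame(columns=["person_id", "drug_code", "start_day", "days_supplied"]),
        condition_occurrences=condition_occurrences,
        covariates=covariates,
        index_day=index_day,
        confounder=confounder,
        truth=truth,
    )


def assign_treatments(db: SimulatedDatabase, config: SimConfig) -> SimulatedDatabase:
    """Assign each person to target or comparator and emit dispensing records.

    The arm is a Bernoulli draw from a logistic model on the baseline
    covariates (plus the unmeasured confounder), which is the confounding
    channel a propensity score must remove.  Each person initiates exactly
    one study drug at their index day, followed by refill records.
    """
    rng = _rng(config, _STREAM_TREATMENT)
    n = config.n_persons

    lp = np.full(n, float(config.treatment_intercept))
    for name, coef in config.treatment_coefs.items():
        lp += coef * db.covariates[name].to_numpy()
    lp += config.confounder.treatment_log_odds * db.confounder.to_numpy()
    p_target = 1.0 / (1.0 + np.exp(-lp))
    arm = rng.random(n) < p_target

    es = config.exposure
    if es.fixed:
        n_refills = np.full(n, int(round(es.n_refills_mean)))
    else:
        n_refills = rng.poisson(es.n_refills_mean, size=n)

    pid = db.persons["person_id"].to_numpy()
    index = db.index_day.to_numpy()
    obs_end = db.observation_periods.set_index("person_id")["end_day"].reindex(pid).to_numpy()
    drug = np.where(arm, config.target_code, config.comparator_code)

    rows_pid, rows_drug, rows_start, rows_supply = [], [], [], []
    for i in range(n):
        start = int(index[i])
        supply = es.days_supplied
        rows_pid.append(pid[i]); rows_drug.append(drug[i])
        rows_start.append(start); rows_supply.append(min(supply, int(obs_end[i]) - start + 1))
        for _ in range(int(n_refills[i])):
            gap = es.refill_gap_mean if es.fixed else rng.poisson(es.refill_gap_mean)
            start = start + supply + int(gap)
            if start > obs_end[i]:
                break
            rows_pid.append(pid[i]); rows_drug.append(drug[i])
            rows_start.append(start); rows_supply.append(min(supply, int(obs_end[i]) - start + 1))
    exposures = pd.DataFrame(
        {
            "person_id": rows_pid,
            "drug_code": rows_drug,
            "start_day": rows_start,
            "days_supplied": rows_supply,
        }
    )
    out = dataclasses.replace(db, drug_exposures=exposures)
    out.truth["arm_share_target"] = float(arm.mean())
    return out


def generate_outcomes(db: SimulatedDatabase, config: SimConfig) -> SimulatedDatabase:
    """Draw first-event times for every configured outcome.

    Event times are exponential with per-person rate
    ``baseline_hazard * exp(covariate effects + arm effect + confounder
    effect)``, clocked from the index day; the recorded event day is
    ``index + ceil(T)``, so an event lands inside a 30-day window exactly
    when T <= 30.  Events past the observation-period end are censored
    (never written).
    """
    known = {c.name for c in config.covariates}
    for o in config.outcomes:
        unknown = set(o.covariate_log_hr) - known
        if unknown:
            raise ConfigError(f"outcome {o.code!r} references unknown covariates: {sorted(unknown)}")

    rng = _rng(config, _STREAM_OUTCOMES)
    pid = db.persons["person_id"].to_numpy()
    arm = db.arms.to_numpy()
    index = db.index_day.to_numpy()
    obs_end = db.observation_periods.set_index("person_id")["end_day"].reindex(pid).to_numpy()
    u = db.confounder.to_numpy()

    rows = []
    for o in config.outcomes:
        lp = np.zeros(len(pid))
        for name, beta in o.covariate_log_hr.items():
            lp += beta * db.covariates[name].to_numpy()
        lp += o.log_hr_target * arm
        lp += o.confounder_log_hr * u
        rate = o.baseline_hazard * np.exp(lp)
        t = rng.exponential(1.0 / rate)
        event_day = index + np.ceil(t).astype(int)
        keep = event_day <= obs_end
        for p, d in zip(pid[keep], event_day[keep]):
            rows.append((p, o.code, int(d)))
    new = pd.DataFrame(rows, columns=["person_id", "condition_code", "day"])
    merged = pd.concat([db.condition_occurrences, new], ignore_index=True).sort_values(
        ["person_id", "day"], kind="stable", ignore_index=True
    )
    return dataclasses.replace(db, condition_occurrences=merged)


def simulate(config: SimConfig) -> SimulatedDatabase:
    """Full generation pass: population, treatments, outcomes."""
    db = generate_population(config)
    db = assign_treatments(db, config)
    db = generate_outcomes(db, config)
    return db


def negative_control_specs(
    n: int,
    baseline_hazard: float = 0.001,
    confounder_log_hr: float = 0.0,
    covariate_log_hr: dict[str, float] | None = None,
) -> tuple[OutcomeSpec, ...]:
    """A batch of negative-control outcomes (true drug effect exactly null)."""
    return tuple(
        OutcomeSpec(
            code=f"nc_{i:03d}",
            baseline_hazard=baseline_hazard,
            log_hr_target=0.0,
            is_negative_control=True,
            confounder_log_hr=confounder_log_hr,
            covariate_log_hr=dict(covariate_log_hr or {}),
        )
        for i in range(1, n + 1)
    )


def simulate_sccs_cases(
    n_persons: int,
    seed: int,
    true_irr: float = 1.0,
    baseline_rate: float = 0.002,
    obs_days: int = 1000,
    era_start: tuple[int, int] = (200, 600),
    era_length: tuple[int, int] = (60, 365),
    frailty_sd: float = 0.0,
    outcome_code: str = "outcome",
    drug_code: str = "target_drug",
) -> dict[str, pd.DataFrame]:
    """Recurrent-event histories for self-controlled case series testing.

    Each person gets one observation period, one exposure era placed
    uniformly inside it, and events from a piecewise-constant Poisson
    process: rate ``baseline_rate * frailty`` off treatment and
    ``baseline_rate * frailty * true_irr`` on treatment.  The multiplicative
    per-person log-normal frailty creates between-person heterogeneity that
    a within-person design must be immune to.
    """
    rng = np.random.default_rng([int(seed), _STREAM_SCCS])
    persons, obs, eras, events = [], [], [], []
    for p in range(1, n_persons + 1):
        persons.append((p, 1960, "F"))
        obs.append((p, 0, obs_days - 1))
        s = int(rng.integers(era_start[0], era_start[1] + 1))
        ln = int(rng.integers(era_length[0], era_length[1] + 1))
        e = min(s + ln - 1, obs_days - 1)
        eras.append((p, drug_code, s, e))
        frailty = math.exp(rng.normal(0.0, frailty_sd)) if frailty_sd > 0 else 1.0
        for a, b, rate in (
            (0, s - 1, baseline_rate * frailty),
            (s, e, baseline_rate * frailty * true_irr),
            (e + 1, obs_days - 1, baseline_rate * frailty),
        ):
            length = b - a + 1
            if length <= 0:
                continue
            k = rng.poisson(rate * length)
            days = rng.integers(a, b + 1, size=k)
            for d in days:
                events.append((p, outcome_code, int(d)))
    return {
        "persons": pd.DataFrame(persons, columns=["person_id", "year_of_birth", "sex"]),
        "observation_periods": pd.DataFrame(obs, columns=["person_id", "start_day", "end_day"]),
        "eras": pd.DataFrame(eras, columns=["person_id", "drug_code", "era_start_day", "era_end_day"]),
        "events": pd.DataFrame(events, columns=["person_id", "condition_code", "day"]),
    }


# ---------------------------------------------------------------------------
# Serialization

_TABLES = ("persons", "observation_periods", "drug_exposures", "condition_occurrences")


def _config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["covariates"] = [dataclasses.asdict(c) for c in config.covariates]
    d["outcomes"] = [dataclasses.asdict(o) for o in config.outcomes]
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "covariates" in d:
        d["covariates"] = tuple(CovariateSpec(**c) for c in d["covariates"])
    if "outcomes" in d:
        d["outcomes"] = tuple(OutcomeSpec(**o) for o in d["outcomes"])
    if "exposure" in d:
        d["exposure"] = ExposureSpec(**d["exposure"])
    if "observation" in d:
        obs = d["observation"]
        obs = {k: tuple(v) for k, v in obs.items()}
        d["observation"] = ObservationSpec(**obs)
    if "confounder" in d:
        d["confounder"] = UnmeasuredConfounder(**d["confounder"])
    for key in ("age_range",):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)


def write_database(db: SimulatedDatabase, outdir: str | pathlib.Path) -> None:
    """Write the four tables as headered UTF-8 CSVs plus a truth.json sidecar."""
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        getattr(db, name).to_csv(out / f"{name}.csv", index=False)
    db.covariates.reset_index().to_csv(out / "covariates.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(db.truth, fh, indent=2, default=float)


def read_database(indir: str | pathlib.Path) -> SimulatedDatabase:
    """Read a directory written by :func:`write_database`."""
    ind = pathlib.Path(indir)
    tables = {name: pd.read_csv(ind / f"{name}.csv") for name in _TABLES}
    covariates = pd.read_csv(ind / "covariates.csv").set_index("person_id")
    with open(ind / "truth.json") as fh:
        truth = json.load(fh)
    first = (
        tables["drug_exposures"].sort_values("start_day").drop_duplicates("person_id")
    )
    index_day = first.set_index("person_id")["start_day"].reindex(covariates.index)
    return SimulatedDatabase(
        persons=tables["persons"],
        observation_periods=tables["observation_periods"],
        drug_exposures=tables["drug_exposures"],
        condition_occurrences=tables["condition_occurrences"],
        covariates=covariates,
        index_day=index_day,
        confounder=pd.Series(0, index=covariates.index, name="confounder"),
        truth=truth,
    )
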