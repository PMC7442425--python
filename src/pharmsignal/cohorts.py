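"""New-user cohort construction: drug eras, eligibility, time at risk.

Dispensing records are stitched into *drug eras* — periods of inferred
continuous exposure — by merging consecutive records whose unexposed gap is
at most ``max_gap_days`` (90 by default).  New users of a target drug are
contrasted with new users of an active comparator; eligibility requires the
indication on or before the index day, age >= 18 at index, and at least 365
days of prior continuous observation.  Follow-up ("time at risk") starts
the day after the index and is truncated either at a fixed horizon
(intention-to-treat, 30 days) or at the end of the first drug era plus a
washout (on-treatment, 14 days).

Intervals are closed ``[start_day, end_day]``; person-time is counted in
days and converted to years (/365.25) only at reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import SimulatedDatabase

__all__ = [
    "DataError",
    "TimeAtRiskSpec",
    "build_drug_eras",
    "select_new_users",
    "compute_time_at_risk",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


class DataError(ValueError):
    """Malformed input rows."""


@dataclass(frozen=True)
class TimeAtRiskSpec:
    """How follow-up windows are carved out of each person's timeline.

    mode
        ``"intention_to_treat"`` ends follow-up ``fixed_end_offset_days``
        after the index; ``"on_treatment"`` follows the first drug era plus
        ``post_exposure_washout_days``.
    """

    mode: str = "intention_to_treat"
    start_offset_days: int = 1
    fixed_end_offset_days: int | None = 30
    post_exposure_washout_days: int = 14
    era_gap_days: int = 90

    def __post_init__(self) -> None:
        if self.mode not in ("intention_to_treat", "on_treatment"):
            raise ValueError(f"unknown time-at-risk mode {self.mode!r}")
        if self.start_offset_days < 0:
            raise ValueError("start_offset_days must be >= 0")
        if self.mode == "intention_to_treat" and self.fixed_end_offset_days is None:
            raise ValueError("intention_to_treat requires fixed_end_offset_days")


def build_drug_eras(exposures: pd.DataFrame, max_gap_days: int = 90) -> pd.DataFrame:
    """Merge dispensing records into eras, tolerating gaps of unexposed days.

    Two consecutive records of the same person and drug are merged when the
    number of unexposed days between them, ``next_start - previous_end - 1``,
    is at most ``max_gap_days``.  An era ends on the last contributing
    record's ``start_day + days_supplied - 1``.

    Returns a frame with columns ``person_id, drug_code, era_start_day,
    era_end_day`` (both days inclusive).
    """
    required = {"person_id", "drug_code", "start_day", "days_supplied"}
    missing = required - set(exposures.columns)
    if missing:
        raise DataError(f"exposure table missing columns: {sorted(missing)}")
    bad = exposures.index[exposures["days_supplied"] < 1]
    if len(bad):
        raise DataError(f"days_supplied < 1 at rows {list(bad[:5])}")

    if exposures.empty:
        return pd.DataFrame(columns=["person_id", "drug_code", "era_start_day", "era_end_day"])

    df = exposures.sort_values(["person_id", "drug_code", "start_day"], kind="stable")
    pid = df["person_id"].to_numpy()
    drug = df["drug_code"].to_numpy()
    start = df["start_day"].to_numpy(dtype=np.int64)
    end = start + df["days_supplied"].to_numpy(dtype=np.int64) - 1

    rows = []
    cur = None  # (pid, drug, era_start, era_end)
    for i in range(len(df)):
        if cur is not None and pid[i] == cur[0] and drug[i] == cur[1] and start[i] - cur[3] - 1 <= max_gap_days:
            cur = (cur[0], cur[1], cur[2], max(cur[3], end[i]))
        else:
            if cur is not None:
                rows.append(cur)
            cur = (pid[i], drug[i], start[i], end[i])
    rows.append(cur)
    return pd.DataFrame(rows, columns=["person_id", "drug_code", "era_start_day", "era_end_day"])


def age_at_day(year_of_birth: np.ndarray, day: np.ndarray, start_year: int) -> np.ndarray:
    """Whole years of age on a given study day (day 0 = Jan 1 of start_year)."""
    return (np.asarray(day) + 365 * (start_year - np.asarray(year_of_birth))) // 365


def select_new_users(
    db: SimulatedDatabase,
    target_code: str,
    comparator_code: str,
    indication_code: str,
    washout_days: int = 365,
    min_age: int = 18,
    eras: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the two-arm new-user cohort.

    The index is the first era start of the person's own drug.  Persons with
    any exposure to the other study drug on or before their index (including
    same-day initiation of both) are excluded, as are persons younger than
    ``min_age`` at index, without the indication recorded on or before the
    index, or with fewer than ``washout_days`` observed days before it.

    Returns one row per included person: ``person_id, arm, index_day,
    age_at_index`` plus the baseline covariate columns.
    """
    if target_code == comparator_code:
        raise ValueError("target and comparator drug codes must differ")
    if eras is None:
        eras = build_drug_eras(db.drug_exposures)
    eras = eras[eras["drug_code"].isin([target_code, comparator_code])]
    if eras.empty:
        return pd.DataFrame(columns=["person_id", "arm", "index_day", "age_at_index"])

    first = (
        eras.groupby(["person_id", "drug_code"])["era_start_day"].min().unstack()
    )
    t0 = first[target_code] if target_code in first else pd.Series(np.nan, index=first.index)
    c0 = first[comparator_code] if comparator_code in first else pd.Series(np.nan, index=first.index)

    # Cleanest new-user contrast: anyone ever exposed to both study drugs
    # (including same-day initiation of both) is excluded entirely rather
    # than censored at crossover.
    both = t0.notna() & c0.notna()
    arm_target = t0.notna() & ~both
    arm_comp = c0.notna() & ~both
    index = pd.Series(np.where(arm_target, t0, c0), index=first.index)
    keep = arm_target | arm_comp

    out = pd.DataFrame(
        {
            "person_id": first.index[keep],
            "arm": np.where(arm_target[keep], "target", "comparator"),
            "index_day": index[keep].astype(int).to_numpy(),
        }
    )

    persons = db.persons.set_index("person_id")
    start_year = int(db.truth["config"].get("start_year", 2010)) if isinstance(db.truth.get("config"), dict) else 2010
    out["age_at_index"] = age_at_day(
        persons.loc[out["person_id"], "year_of_birth"].to_numpy(),
        out["index_day"].to_numpy(),
        start_year,
    )

    obs = db.observation_periods.set_index("person_id")
    obs_start = obs.loc[out["person_id"], "start_day"].to_numpy()
    obs_end = obs.loc[out["person_id"], "end_day"].to_numpy()

    ind = db.condition_occurrences
    ind = ind[ind["condition_code"] == indication_code]
    first_ind = ind.groupby("person_id")["day"].min()
    ind_day = first_ind.reindex(out["person_id"]).to_numpy()

    ok_age = out["age_at_index"].to_numpy() >= min_age
    ok_ind = ~np.isnan(ind_day) & (ind_day <= out["index_day"].to_numpy())
    ok_washout = out["index_day"].to_numpy() - obs_start >= washout_days
    ok_obs = (out["index_day"].to_numpy() >= obs_start) & (out["index_day"].to_numpy() <= obs_end)
    out = out[ok_age & ok_ind & ok_washout & ok_obs].reset_index(drop=True)

    out = out.merge(db.covariates.reset_index(), on="person_id", how="left")
    return out


def compute_time_at_risk(
    entries: pd.DataFrame,
    eras: pd.DataFrame,
    outcomes: pd.DataFrame,
    spec: TimeAtRiskSpec,
    observation_periods: pd.DataFrame,
) -> pd.DataFrame:
    """Realize one risk interval per cohort entry for a single outcome.

    ``outcomes`` holds condition occurrences of the outcome of interest
    (columns ``person_id, day``).  Follow-up runs from ``index +
    start_offset_days`` to the first of: the first qualifying event, the end
    of observation, and either the fixed horizon (ITT) or the first drug
    era's end plus the washout (on-treatment).  Entries whose window closes
    before it opens (e.g. observation ends on the index day) are dropped
    with a logged reason.

    Returns ``person_id, arm, start_day, end_day, event, event_day,
    person_days``.
    """
    if entries.empty:
        return pd.DataFrame(
            columns=["person_id", "arm", "start_day", "end_day", "event", "event_day", "person_days"]
        )
    obs_end = observation_periods.set_index("person_id")["end_day"]
    index = entries["index_day"].to_numpy()
    pid = entries["person_id"].to_numpy()
    start = index + spec.start_offset_days

    if spec.mode == "intention_to_treat":
        cap = index + int(spec.fixed_end_offset_days)
    else:
        era_end = _index_era_end(eras, pid, index)
        cap = era_end + spec.post_exposure_washout_days

    end = np.minimum(cap, obs_end.reindex(pid).to_numpy())

    ev = outcomes[["person_id", "day"]].sort_values("day", kind="stable")
    rows = []
    ev_by_pid = {p: g["day"].to_numpy() for p, g in ev.groupby("person_id")}
    n_dropped = 0
    for i in range(len(entries)):
        s, e = int(start[i]), int(end[i])
        if e < s:
            n_dropped += 1
            continue
        days = ev_by_pid.get(pid[i])
        event_day = None
        if days is not None:
            inwin = days[(days >= s) & (days <= e)]
            if len(inwin):
                event_day = int(inwin.min())
                e = event_day
        rows.append(
            (
                pid[i],
                entries["arm"].iat[i],
                s,
                e,
                event_day is not None,
                event_day,
                e - s + 1,
            )
        )
    if n_dropped:
        logger.info("dropped %d entries with empty risk windows (end < start)", n_dropped)
    return pd.DataFrame(
        rows, columns=["person_id", "arm", "start_day", "end_day", "event", "event_day", "person_days"]
    )


def _index_era_end(eras: pd.DataFrame, pid: np.ndarray, index: np.ndarray) -> np.ndarray:
    """End day of the era that starts at each person's index."""
    key = eras.set_index(["person_id", "era_start_day"])["era_end_day"]
    out = np.empty(len(pid), dtype=np.int64)
    for i, (p, d) in enumerate(zip(pid, index)):
        try:
            out[i] = key.loc[(p, d)]
        except KeyError:
            out[i] = d  # defensive: no era found, treat index day as era end
    return out
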