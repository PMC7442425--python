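"""Hazard-ratio estimation within propensity strata, rates, and power.

The effect of target vs comparator initiation is estimated by a Cox
proportional-hazards model conditioned on the propensity strata (a separate
baseline hazard per stratum, a single treatment coefficient), with Efron
handling of tied event times — ties are guaranteed because person-time is
in integer days.  Analyses with zero events in either arm are inestimable
and are returned as exclusion records rather than numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .cohorts import DAYS_PER_YEAR

__all__ = [
    "EstimationResult",
    "fit_stratified_cox",
    "incidence_rate",
    "minimum_detectable_rr",
]

Z975 = 1.959964


@dataclass
class EstimationResult:
    """One analysis's hazard-ratio estimate (or its exclusion record)."""

    analysis_id: str
    log_hr: float | None
    se_log_hr: float | None
    hr: float | None
    ci95_low: float | None
    ci95_high: float | None
    p_two_sided: float | None
    events_target: int
    events_comparator: int
    persondays_target: int
    persondays_comparator: int
    excluded: bool = False
    reason: str | None = None

    @classmethod
    def exclusion(cls, analysis_id, reason, events_t=0, events_c=0, pd_t=0, pd_c=0):
        return cls(
            analysis_id=analysis_id,
            log_hr=None, se_log_hr=None, hr=None,
            ci95_low=None, ci95_high=None, p_two_sided=None,
            events_target=events_t, events_comparator=events_c,
            persondays_target=pd_t, persondays_comparator=pd_c,
            excluded=True, reason=reason,
        )


def fit_stratified_cox(
    risk_intervals: pd.DataFrame,
    strata: np.ndarray | pd.Series,
    analysis_id: str = "analysis",
) -> EstimationResult:
    """Cox model of event hazard on arm, stratified on propensity stratum.

    ``risk_intervals`` needs columns ``arm`` ("target"/"comparator" or 0/1),
    ``person_days`` and ``event``; ``strata`` aligns positionally.  Returns
    an exclusion record when either arm has zero events or the partial
    likelihood cannot be maximized (separation / non-convergence).
    """
    df = pd.DataFrame(
        {
            "duration": risk_intervals["person_days"].to_numpy(dtype=float),
            "event": risk_intervals["event"].to_numpy(dtype=bool),
            "arm": _arm01(risk_intervals["arm"]),
            "stratum": np.asarray(strata),
        }
    )
    ev_t = int(df.loc[df["arm"] == 1, "event"].sum())
    ev_c = int(df.loc[df["arm"] == 0, "event"].sum())
    pd_t = int(df.loc[df["arm"] == 1, "duration"].sum())
    pd_c = int(df.loc[df["arm"] == 0, "duration"].sum())
    if ev_t == 0 or ev_c == 0:
        return EstimationResult.exclusion(analysis_id, "zero events in an arm", ev_t, ev_c, pd_t, pd_c)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df, duration_col="duration", event_col="event", strata=["stratum"], formula="arm")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return EstimationResult.exclusion(
            analysis_id, "separation/nonconvergence", ev_t, ev_c, pd_t, pd_c
        )

    beta = float(cph.params_["arm"])
    se = float(cph.standard_errors_["arm"])
    if not np.isfinite(beta) or not np.isfinite(se) or se <= 0:
        return EstimationResult.exclusion(
            analysis_id, "separation/nonconvergence", ev_t, ev_c, pd_t, pd_c
        )
    return EstimationResult(
        analysis_id=analysis_id,
        log_hr=beta,
        se_log_hr=se,
        hr=float(np.exp(beta)),
        ci95_low=float(np.exp(beta - Z975 * se)),
        ci95_high=float(np.exp(beta + Z975 * se)),
        p_two_sided=float(2 * stats.norm.sf(abs(beta / se))),
        events_target=ev_t,
        events_comparator=ev_c,
        persondays_target=pd_t,
        persondays_comparator=pd_c,
    )


def _arm01(arm: pd.Series) -> np.ndarray:
    arr = np.asarray(arm)
    if arr.dtype.kind in "OUS":
        return (arr == "target").astype(float)
    return arr.astype(float)


def incidence_rate(events: int, person_days: float) -> float:
    """Events per 1000 person-years."""
    if events < 0 or person_days < 0:
        raise ValueError("events and person_days must be non-negative")
    if person_days == 0:
        if events == 0:
            return 0.0
        raise ValueError("events > 0 with zero person-time")
    return events / (person_days / DAYS_PER_YEAR) * 1000.0


def minimum_detectable_rr(
    events_total: int,
    ratio_persontime: float = 1.0,
    alpha: float = 0.05,
    power: float = 0.8,
) -> float:
    """Smallest rate ratio detectable with the given events and power.

    Two-sided normal approximation on the log-rate-ratio scale with the
    event split taken under the null (events land in the target arm with
    probability ``r / (r + 1)``, r = target:comparator person-time ratio):
    ``log MDRR = (z_{1-a/2} + z_{power}) * sqrt(1/E_t + 1/E_c)``.  Strictly
    decreasing in ``events_total``; infinite at zero events.
    """
    if events_total < 0:
        raise ValueError("events_total must be >= 0")
    if events_total == 0:
        return float("inf")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    r = float(ratio_persontime)
    p0 = r / (r + 1.0)
    se = np.sqrt(1.0 / (events_total * p0) + 1.0 / (events_total * (1.0 - p0)))
    return float(np.exp((za + zb) * se))
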