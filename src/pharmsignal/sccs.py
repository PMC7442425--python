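"""Self-controlled case series (SCCS) estimation.

The SCCS design compares event rates within a person between exposed and
unexposed time, eliminating all time-invariant confounding (including
unmeasured between-person differences).  Each person's observation time is
partitioned at exposure-era boundaries, age-band birthdays, season
boundaries and co-medication era boundaries; conditioning on the person's
total event count turns the Poisson likelihood into a per-person
multinomial over intervals with probabilities proportional to
``length * exp(x'beta)`` — any multiplicative per-person frailty cancels
exactly.  The exposure coefficient is unregularized; nuisance covariates
(age, season, co-drugs) carry an L1 penalty selected by seeded ten-fold
cross-validation over cases, mirroring large-scale regularized fitting
practice for this design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.model_selection import KFold

from .cohorts import DataError

__all__ = ["SccsResult", "build_sccs_intervals", "fit_sccs"]

Z975 = 1.959964
SEASON_BOUNDARIES = (0, 91, 182, 273)  # day-of-year starts of calendar quarters


@dataclass
class SccsResult:
    log_irr: float | None
    se: float | None
    irr: float | None
    ci95_low: float | None
    ci95_high: float | None
    p: float | None
    n_cases: int
    n_events_exposed: int
    n_events_unexposed: int
    excluded: bool = False
    reason: str | None = None


def _season_of_day(day: np.ndarray) -> np.ndarray:
    doy = np.asarray(day) % 365
    return np.searchsorted(SEASON_BOUNDARIES, doy, side="right") - 1


def build_sccs_intervals(
    observation_periods: pd.DataFrame,
    exposure_eras: pd.DataFrame,
    events: pd.DataFrame,
    persons: pd.DataFrame | None = None,
    age_band_years: int | None = 5,
    seasons: bool = True,
    co_drug_eras: dict[str, pd.DataFrame] | None = None,
    start_year: int = 2010,
) -> pd.DataFrame:
    """Partition each person's observation time into homogeneous intervals.

    Cut points are placed at every exposure-era start and end, every
    age-band birthday (``age_band_years`` wide bands; None disables), every
    calendar-quarter boundary (365-day years anchored at Jan 1 of
    ``start_year``; ``seasons=False`` disables) and every co-drug era
    boundary.  Each event is assigned to the unique interval containing its
    day; an event outside its person's observation period is a data error.

    Returns columns ``person_id, start_day, end_day, exposed, age_band,
    season, co_<code>..., n_events, length_days``; interval lengths sum to
    each person's observation length exactly.
    """
    if age_band_years is not None and persons is None:
        raise ValueError("age bands require the persons table (year_of_birth)")
    yob = persons.set_index("person_id")["year_of_birth"] if persons is not None else None
    eras_by_pid = {p: g for p, g in exposure_eras.groupby("person_id")}
    events_by_pid = {p: g["day"].to_numpy() for p, g in events.groupby("person_id")}
    co_by_pid = {
        code: {p: g for p, g in frame.groupby("person_id")}
        for code, frame in (co_drug_eras or {}).items()
    }

    rows = []
    for _, op in observation_periods.iterrows():
        p, obs_s, obs_e = int(op["person_id"]), int(op["start_day"]), int(op["end_day"])
        ev = events_by_pid.get(p, np.array([], dtype=int))
        if len(ev) and (ev.min() < obs_s or ev.max() > obs_e):
            raise DataError(f"event outside observation period for person {p}")

        cuts = {obs_s, obs_e + 1}
        era = eras_by_pid.get(p)
        if era is not None:
            for s, e in zip(era["era_start_day"], era["era_end_day"]):
                cuts.add(max(int(s), obs_s))
                cuts.add(min(int(e) + 1, obs_e + 1))
        if seasons:
            for k in range((obs_e // 365) + 2):
                for b in SEASON_BOUNDARIES:
                    d = 365 * k + b
                    if obs_s < d <= obs_e:
                        cuts.add(d)
        if age_band_years is not None:
            offset = 365 * (start_year - int(yob.loc[p]))
            period = 365 * age_band_years
            # band birthdays: days d with (d + offset) % period == 0
            first = -offset % period
            d = first
            while d <= obs_e:
                if obs_s < d:
                    cuts.add(d)
                d += period
        for code, frames in co_by_pid.items():
            co = frames.get(p)
            if co is not None:
                for s, e in zip(co["era_start_day"], co["era_end_day"]):
                    if int(s) > obs_e or int(e) < obs_s:
                        continue
                    cuts.add(max(int(s), obs_s))
                    cuts.add(min(int(e) + 1, obs_e + 1))

        bounds = sorted(cuts)
        for a, b in zip(bounds[:-1], bounds[1:]):
            s_day, e_day = a, b - 1
            exposed = False
            if era is not None:
                exposed = bool(
                    ((era["era_start_day"] <= s_day) & (era["era_end_day"] >= s_day)).any()
                )
            row = {
                "person_id": p,
                "start_day": s_day,
                "end_day": e_day,
                "exposed": exposed,
                "n_events": int(((ev >= s_day) & (ev <= e_day)).sum()),
                "length_days": e_day - s_day + 1,
            }
            if seasons:
                row["season"] = int(_season_of_day(np.array([s_day]))[0])
            if age_band_years is not None:
                age = (s_day + 365 * (start_year - int(yob.loc[p]))) // 365
                row["age_band"] = int(age // age_band_years)
            for code, frames in co_by_pid.items():
                co = frames.get(p)
                on = False
                if co is not None:
                    on = bool(((co["era_start_day"] <= s_day) & (co["era_end_day"] >= s_day)).any())
                row[f"co_{code}"] = on
            rows.append(row)
    return pd.DataFrame(rows)


def _design(intervals: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Exposure column first, then nuisance dummies (reference level dropped)."""
    cols = [intervals["exposed"].to_numpy(dtype=float)]
    names = ["exposed"]
    for cat in ("age_band", "season"):
        if cat in intervals.columns:
            levels = sorted(intervals[cat].unique())
            for lev in levels[1:]:
                cols.append((intervals[cat] == lev).to_numpy(dtype=float))
                names.append(f"{cat}_{lev}")
    for c in intervals.columns:
        if c.startswith("co_"):
            cols.append(intervals[c].to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(cols), names


class _ConditionalPoisson:
    """Per-person multinomial (conditional Poisson) likelihood machinery.

    All per-person reductions are segment operations (``np.*.reduceat``
    over contiguous person blocks) so likelihood, gradient and Hessian
    evaluations stay vectorized at any number of cases.
    """

    def __init__(self, X: np.ndarray, length: np.ndarray, n_events: np.ndarray, person: np.ndarray):
        order = np.argsort(person, kind="stable")
        self.X = np.ascontiguousarray(X[order])
        self.log_l = np.log(length[order].astype(float))
        self.n = n_events[order].astype(float)
        pers = np.asarray(person)[order]
        change = np.flatnonzero(pers[1:] != pers[:-1]) + 1
        self.starts = np.concatenate([[0], change])
        self.counts = np.diff(np.concatenate([self.starts, [len(pers)]]))
        self.N = np.add.reduceat(self.n, self.starts)

    def _softmax(self, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Within-person softmax probabilities and per-person logsumexp."""
        m = np.maximum.reduceat(eta, self.starts)
        em = np.exp(eta - np.repeat(m, self.counts))
        s = np.add.reduceat(em, self.starts)
        return em / np.repeat(s, self.counts), m + np.log(s)

    def nll(self, beta: np.ndarray) -> float:
        eta = self.X @ beta + self.log_l
        _, lse = self._softmax(eta)
        return -(float(np.sum(self.n * eta)) - float(np.sum(self.N * lse)))

    def grad(self, beta: np.ndarray) -> np.ndarray:
        eta = self.X @ beta + self.log_l
        p, _ = self._softmax(eta)
        expected = np.repeat(self.N, self.counts) * p
        return -(self.X.T @ (self.n - expected))

    def hessian(self, beta: np.ndarray) -> np.ndarray:
        eta = self.X @ beta + self.log_l
        p, _ = self._softmax(eta)
        w = np.repeat(self.N, self.counts) * p
        # sum_i N_i (X_i' diag(p_i) X_i - xp_i xp_i'), xp_i = X_i' p_i
        first = self.X.T @ (self.X * w[:, None])
        xp = np.add.reduceat(self.X * p[:, None], self.starts, axis=0)
        second = (xp * self.N[:, None]).T @ xp
        return first - second


def _fit_l1(
    lik: _ConditionalPoisson, n_params: int, penalty: float, penalized: np.ndarray
) -> np.ndarray:
    """Minimize nll + penalty * sum|beta_penalized| via positive/negative split."""
    k = int(penalized.sum())
    if k == 0 or penalty == 0:
        res = optimize.minimize(
            lik.nll, np.zeros(n_params), jac=lik.grad, method="BFGS",
            options={"gtol": 1e-12, "maxiter": 500},
        )
        return res.x

    pen_idx = np.flatnonzero(penalized)

    def unpack(theta: np.ndarray) -> np.ndarray:
        beta = np.array(theta[:n_params])
        beta[pen_idx] = theta[n_params : n_params + k] - theta[n_params + k :]
        return beta

    def f(theta):
        beta = unpack(theta)
        return lik.nll(beta) + penalty * np.sum(theta[n_params:])

    def g(theta):
        beta = unpack(theta)
        gb = lik.grad(beta)
        out = np.empty_like(theta)
        out[:n_params] = gb
        out[pen_idx] = 0.0
        out[n_params : n_params + k] = gb[pen_idx] + penalty
        out[n_params + k :] = -gb[pen_idx] + penalty
        return out

    bounds = [(None, None)] * n_params + [(0, None)] * (2 * k)
    theta0 = np.zeros(n_params + 2 * k)
    res = optimize.minimize(
        f, theta0, jac=g, method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 1000},
    )
    return unpack(res.x)


def fit_sccs(
    intervals: pd.DataFrame,
    regularize_covariates: bool = True,
    cv_folds: int = 10,
    seed: int = 0,
    penalty_grid: np.ndarray | None = None,
) -> SccsResult:
    """Fit the conditional Poisson SCCS model and return the exposure IRR.

    Only cases (persons with >= 1 event) contribute.  The exposure
    coefficient is never penalized; nuisance covariates are L1-penalized
    with the penalty chosen by ``cv_folds``-fold cross-validated out-of-fold
    conditional log-likelihood over cases (deterministic given ``seed``).
    Inestimable configurations (no exposed time among cases, or all events
    on one side with separation) are returned flagged rather than raised.
    """
    cases = intervals.groupby("person_id")["n_events"].sum()
    case_ids = cases.index[cases > 0]
    n_cases = len(case_ids)
    if n_cases == 0:
        return SccsResult(None, None, None, None, None, None, 0, 0, 0, True, "no cases")
    df = intervals[intervals["person_id"].isin(case_ids)].reset_index(drop=True)

    ev_exp = int(df.loc[df["exposed"].astype(bool), "n_events"].sum())
    ev_unexp = int(df.loc[~df["exposed"].astype(bool), "n_events"].sum())
    exp_time = df.loc[df["exposed"].astype(bool), "length_days"].sum()
    unexp_time = df.loc[~df["exposed"].astype(bool), "length_days"].sum()
    if exp_time == 0 or unexp_time == 0:
        return SccsResult(
            None, None, None, None, None, None, n_cases, ev_exp, ev_unexp,
            True, "no exposed (or unexposed) person-time among cases",
        )
    if ev_exp == 0 and ev_unexp == 0:
        return SccsResult(None, None, None, None, None, None, n_cases, 0, 0, True, "no events")

    X, names = _design(df)
    person = df["person_id"].to_numpy()
    lik = _ConditionalPoisson(X, df["length_days"].to_numpy(), df["n_events"].to_numpy(), person)
    p = X.shape[1]
    penalized = np.zeros(p, dtype=bool)
    penalized[1:] = regularize_covariates

    if penalized.any():
        grid = penalty_grid
        if grid is None:
            # lambda_max: score of the nuisance block at the exposure-only fit
            lik1 = _ConditionalPoisson(
                X[:, :1], df["length_days"].to_numpy(), df["n_events"].to_numpy(), person
            )
            res1 = optimize.minimize(lik1.nll, np.zeros(1), jac=lik1.grad, method="BFGS")
            beta0 = np.zeros(p)
            beta0[0] = res1.x[0]
            g0 = max(float(np.abs(lik.grad(beta0)[penalized]).max()), 1e-3)
            grid = np.geomspace(g0 * 1.05, g0 * 1e-4, 10)
        best_pen, best_score = None, -np.inf
        rng_folds = KFold(n_splits=min(cv_folds, n_cases), shuffle=True, random_state=seed)
        ids = np.asarray(case_ids)
        folds = list(rng_folds.split(ids))
        for pen in grid:
            score = 0.0
            for train_idx, test_idx in folds:
                tr = df["person_id"].isin(ids[train_idx]).to_numpy()
                te = ~tr
                lik_tr = _ConditionalPoisson(
                    X[tr], df["length_days"].to_numpy()[tr], df["n_events"].to_numpy()[tr], person[tr]
                )
                beta = _fit_l1(lik_tr, p, pen, penalized)
                lik_te = _ConditionalPoisson(
                    X[te], df["length_days"].to_numpy()[te], df["n_events"].to_numpy()[te], person[te]
                )
                score -= lik_te.nll(beta)
            if score > best_score:
                best_score, best_pen = score, pen
        beta = _fit_l1(lik, p, best_pen, penalized)
    else:
        beta = _fit_l1(lik, p, 0.0, penalized)

    if not np.all(np.isfinite(beta)) or abs(beta[0]) > 20:
        return SccsResult(
            None, None, None, None, None, None, n_cases, ev_exp, ev_unexp,
            True, "separation/nonconvergence",
        )
    H = lik.hessian(beta)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return SccsResult(
            None, None, None, None, None, None, n_cases, ev_exp, ev_unexp,
            True, "singular information matrix",
        )
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    b = float(beta[0])
    if se == 0 or not np.isfinite(se):
        return SccsResult(
            None, None, None, None, None, None, n_cases, ev_exp, ev_unexp,
            True, "degenerate variance",
        )
    return SccsResult(
        log_irr=b,
        se=se,
        irr=float(np.exp(b)),
        ci95_low=float(np.exp(b - Z975 * se)),
        ci95_high=float(np.exp(b + Z975 * se)),
        p=float(2 * stats.norm.sf(abs(b / se))),
        n_cases=n_cases,
        n_events_exposed=ev_exp,
        n_events_unexposed=ev_unexp,
    )
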