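"""Regularized propensity scores, quintile stratification, balance checks.

The propensity score — the probability of initiating the target drug given
baseline covariates — is fitted by L1-penalized (LASSO) logistic regression
with the penalty chosen by seeded ten-fold cross-validation on out-of-fold
log-likelihood.  Scores are cut into quintiles of the pooled distribution,
and covariate balance before/after stratification is summarized by
standardized mean differences (SMD); any |SMD| > 0.1 after stratification
fails the analysis, which downstream drivers treat as an exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "EstimationError",
    "PropensityModel",
    "BalanceReport",
    "fit_propensity_model",
    "stratify_by_quintile",
    "standardized_mean_difference",
    "balance_report",
]

SMD_THRESHOLD = 0.1
_SCORE_EPS = 1e-12


class EstimationError(RuntimeError):
    pass


@dataclass
class PropensityModel:
    coefficients: pd.Series
    intercept: float
    selected_penalty: float  # lambda = 1 / C, on the sklearn scale
    cv_folds: int
    scores: pd.Series  # per-person P(target | covariates), in (0,1)


@dataclass
class BalanceReport:
    table: pd.DataFrame  # index: covariate; columns: mean_target/comparator (+_after), smd_before, smd_after
    max_abs_smd_after: float
    passed: bool


def fit_propensity_model(
    covariates: pd.DataFrame,
    arm_labels: np.ndarray | pd.Series,
    folds: int = 10,
    seed: int = 0,
    n_penalties: int = 20,
) -> PropensityModel:
    """LASSO logistic propensity model with CV-selected penalty.

    The penalty grid is logarithmic with ``n_penalties`` points over a
    data-driven range; the CV objective is out-of-fold log-likelihood and
    fold assignment is seeded, so repeated fits are identical.  Perfect
    separation (scores saturating at 0/1) falls back to the largest penalty
    on the grid with a warning.
    """
    X = np.asarray(covariates, dtype=float)
    y = _binary_labels(arm_labels)
    if not np.all(np.isfinite(X)):
        raise EstimationError("covariate matrix contains non-finite values")
    n1 = int(y.sum())
    if n1 < 2 or len(y) - n1 < 2:
        raise EstimationError("need at least 2 persons per arm to fit a propensity model")

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    Cs = np.logspace(-4, 4, n_penalties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)
        model = LogisticRegressionCV(
            Cs=Cs,
            cv=cv,
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            max_iter=1000,
            refit=True,
        )
        model.fit(X, y)
    scores = model.predict_proba(X)[:, 1]

    if scores.min() <= _SCORE_EPS or scores.max() >= 1 - _SCORE_EPS:
        warnings.warn(
            "propensity scores saturated (possible separation); refitting at the largest penalty",
            RuntimeWarning,
            stacklevel=2,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", FutureWarning)
            fallback = LogisticRegression(
                C=float(Cs.min()), penalty="l1", solver="liblinear", max_iter=1000
            )
            fallback.fit(X, y)
        model.coef_ = fallback.coef_
        model.intercept_ = fallback.intercept_
        model.C_ = np.array([Cs.min()])
        scores = fallback.predict_proba(X)[:, 1]

    scores = np.clip(scores, _SCORE_EPS, 1 - _SCORE_EPS)
    idx = covariates.index if isinstance(covariates, pd.DataFrame) else pd.RangeIndex(len(y))
    cols = covariates.columns if isinstance(covariates, pd.DataFrame) else pd.RangeIndex(X.shape[1])
    return PropensityModel(
        coefficients=pd.Series(model.coef_.ravel(), index=cols),
        intercept=float(model.intercept_[0]),
        selected_penalty=float(1.0 / model.C_[0]),
        cv_folds=folds,
        scores=pd.Series(scores, index=idx, name="propensity_score"),
    )


def _binary_labels(arm_labels) -> np.ndarray:
    arr = np.asarray(arm_labels)
    if arr.dtype.kind in "OUS":
        return (arr == "target").astype(int)
    return arr.astype(int)


def stratify_by_quintile(scores: np.ndarray | pd.Series, n_strata: int = 5) -> np.ndarray:
    """Assign strata 1..n by quantile cuts of the pooled score distribution.

    Cuts sit at the 20/40/60/80 percentiles for quintiles; a person falls in
    stratum s when their score exceeds the (s-1)-th cut.  Degenerate
    all-equal scores collapse into stratum 1 with a warning.
    """
    s = np.asarray(scores, dtype=float)
    if len(s) < n_strata:
        raise ValueError(f"need at least {n_strata} persons to form {n_strata} strata")
    cuts = np.quantile(s, np.linspace(0, 1, n_strata + 1)[1:-1])
    if s.max() == s.min():
        warnings.warn("all propensity scores identical; single stratum", RuntimeWarning, stacklevel=2)
        return np.ones(len(s), dtype=int)
    return 1 + np.searchsorted(cuts, s, side="left").astype(int)


def standardized_mean_difference(
    values_target: np.ndarray,
    values_comparator: np.ndarray,
    strata_target: np.ndarray | None = None,
    strata_comparator: np.ndarray | None = None,
) -> float:
    """Signed SMD: (mean_t - mean_c) / sqrt((var_t + var_c) / 2).

    When strata are given, arm means are replaced by stratum-size-weighted
    averages of within-stratum means (weights proportional to combined
    stratum size), while the denominator keeps the unadjusted variances so
    that before/after values share a scale.  Zero pooled variance with
    unequal means returns +/-inf as an imbalance flag.
    """
    t = np.asarray(values_target, dtype=float)
    c = np.asarray(values_comparator, dtype=float)
    if len(t) == 0 or len(c) == 0:
        raise ValueError("need at least one value per arm")
    denom = np.sqrt((t.var(ddof=0) + c.var(ddof=0)) / 2.0)

    if strata_target is None:
        diff = t.mean() - c.mean()
    else:
        st = np.asarray(strata_target)
        sc = np.asarray(strata_comparator)
        strata = np.union1d(st, sc)
        weights = np.array([(st == k).sum() + (sc == k).sum() for k in strata], dtype=float)
        weights /= weights.sum()
        diff = 0.0
        for w, k in zip(weights, strata):
            mt = t[st == k].mean() if (st == k).any() else 0.0
            mc = c[sc == k].mean() if (sc == k).any() else 0.0
            diff += w * (mt - mc)

    if denom == 0:
        return 0.0 if diff == 0 else float(np.sign(diff)) * float("inf")
    return float(diff / denom)


def balance_report(
    covariates: pd.DataFrame,
    arms: np.ndarray | pd.Series,
    strata: np.ndarray,
    threshold: float = SMD_THRESHOLD,
) -> BalanceReport:
    """Per-covariate SMD before and after stratification, with a pass flag.

    ``passed`` is True exactly when every |SMD after| <= ``threshold``
    (0.1); pipeline drivers use a failing report to exclude the analysis.
    An empty covariate set passes vacuously (with a warning).
    """
    y = _binary_labels(arms).astype(bool)
    strata = np.asarray(strata)
    if covariates.shape[1] == 0:
        warnings.warn("empty covariate set: balance passes vacuously", RuntimeWarning, stacklevel=2)
        empty = pd.DataFrame(columns=["mean_target", "mean_comparator", "smd_before", "smd_after"])
        return BalanceReport(table=empty, max_abs_smd_after=0.0, passed=True)

    rows = {}
    for name in covariates.columns:
        v = covariates[name].to_numpy(dtype=float)
        before = standardized_mean_difference(v[y], v[~y])
        after = standardized_mean_difference(v[y], v[~y], strata[y], strata[~y])
        rows[name] = {
            "mean_target": v[y].mean(),
            "mean_comparator": v[~y].mean(),
            "smd_before": before,
            "smd_after": after,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    max_after = float(table["smd_after"].abs().max())
    return BalanceReport(table=table, max_abs_smd_after=max_after, passed=bool(max_after <= threshold))
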