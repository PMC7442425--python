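"""Empirical calibration against negative-control outcomes.

Negative controls are outcomes with no causal relation to either study
drug, so any systematic departure of their estimates from the null measures
residual bias.  The empirical null models each control's log effect as
Normal(mu, tau^2 + se_i^2): mu is the mean systematic error, tau its
between-outcome spread, both on the log-HR scale and assumed independent of
true effect size.  Calibrated p-values are tail probabilities under that
null; calibrated estimates shift by -mu and widen the CI by tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "NullDistribution",
    "fit_empirical_null",
    "calibrate_p",
    "calibrate_estimate",
]

Z975 = 1.959964


@dataclass(frozen=True)
class NullDistribution:
    """Empirical systematic-error distribution on the log-HR scale."""

    mu: float
    tau: float
    n_controls: int
    fit_loglik: float


class CalibrationSkipped(RuntimeWarning):
    pass


def fit_empirical_null(
    nc_estimates: list[tuple[float, float]] | np.ndarray,
    min_controls: int = 5,
) -> NullDistribution | None:
    """Maximum-likelihood fit of (mu, tau) from negative-control estimates.

    ``nc_estimates`` is a sequence of (log_hr, se) pairs from outcomes whose
    true effect is null.  The likelihood is the product of
    Normal(log_hr_i; mu, tau^2 + se_i^2) densities, maximized by bounded
    quasi-Newton on (mu, log tau) with an exact check of the tau = 0
    boundary.  Returns None (with a warning) below ``min_controls`` usable
    estimates; callers must then flag results as uncalibrated.
    """
    arr = np.asarray(
        [(lh, se) for lh, se in nc_estimates if np.isfinite(lh) and np.isfinite(se) and se > 0],
        dtype=float,
    )
    if len(arr) < min_controls:
        warnings.warn(
            f"only {len(arr)} usable negative-control estimates (< {min_controls}); "
            "calibration skipped",
            CalibrationSkipped,
            stacklevel=2,
        )
        return None
    theta, se = arr[:, 0], arr[:, 1]

    def nll(params: np.ndarray) -> float:
        mu, log_tau = params
        var = np.exp(2 * log_tau) + se**2
        return float(0.5 * np.sum(np.log(2 * np.pi * var) + (theta - mu) ** 2 / var))

    tau0 = max(np.std(theta), 1e-3)
    best = None
    for start_tau in (tau0, tau0 / 10, tau0 * 3):
        res = optimize.minimize(
            nll,
            x0=np.array([np.mean(theta), np.log(start_tau)]),
            method="L-BFGS-B",
            bounds=[(None, None), (np.log(1e-8), np.log(1e3))],
        )
        if best is None or res.fun < best.fun:
            best = res
    mu_hat, tau_hat = best.x[0], float(np.exp(best.x[1]))

    # tau = 0 boundary: the MLE of mu is then the precision-weighted mean.
    w = 1.0 / se**2
    mu0 = float(np.sum(w * theta) / np.sum(w))
    nll0 = float(0.5 * np.sum(np.log(2 * np.pi * se**2) + (theta - mu0) ** 2 / se**2))
    if nll0 <= best.fun or tau_hat < 1e-6:
        if nll0 <= best.fun:
            mu_hat, tau_hat = mu0, 0.0
        else:
            tau_hat = 0.0
        loglik = -min(nll0, best.fun)
    else:
        loglik = -best.fun
    return NullDistribution(mu=float(mu_hat), tau=tau_hat, n_controls=len(arr), fit_loglik=loglik)


def calibrate_p(log_hr: float, se: float, null: NullDistribution) -> float:
    """Two-sided p-value under the empirical null Normal(mu, tau^2 + se^2).

    Reduces to the standard Wald p when mu = 0 and tau = 0; equals 1 when
    the observed log effect sits exactly at mu with tau = 0.
    """
    sd = np.sqrt(null.tau**2 + se**2)
    if sd == 0:
        return 1.0 if log_hr == null.mu else 0.0
    z = (log_hr - null.mu) / sd
    return float(min(1.0, 2 * stats.norm.sf(abs(z))))


def calibrate_estimate(log_hr: float, se: float, null: NullDistribution) -> dict[str, float]:
    """Calibrated point estimate and 95% CI.

    The calibrated interval is the set of true effects theta for which the
    observed log_hr lies within the central 95% of
    Normal(theta + mu, tau^2 + se^2): point estimate ``log_hr - mu``,
    half-width ``1.959964 * sqrt(tau^2 + se^2)``.
    """
    sd = np.sqrt(null.tau**2 + se**2)
    point = log_hr - null.mu
    return {
        "calibrated_log_hr": float(point),
        "calibrated_se": float(sd),
        "calibrated_hr": float(np.exp(point)),
        "calibrated_ci95_low": float(np.exp(point - Z975 * sd)),
        "calibrated_ci95_high": float(np.exp(point + Z975 * sd)),
        "calibrated_p": calibrate_p(log_hr, se, null),
    }
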