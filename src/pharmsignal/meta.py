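"""Across-database evidence synthesis with an I-squared gate.

Per-database estimates are pooled by DerSimonian-Laird random-effects
meta-analysis: the between-database variance tau^2 is the moment estimate
obtained by comparing each database-specific result with the
inverse-variance fixed-effects mean, and the pooled standard error
incorporates it.  Pooling is withheld ("gated") whenever I^2 >= 0.4 —
heterogeneous drug-outcome pairs are reported per database only.  Patient
and event counts sum across databases and pooled incidence rates are
person-time weighted; cell counts below five are masked as "<5" with any
rate computed from a masked count rendered as a "<" upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaResult",
    "MaskedCount",
    "heterogeneity",
    "random_effects_pool",
    "meta_analysis",
    "pool_counts_and_rates",
    "mask_small_counts",
    "mask_rate",
    "forest_data",
]

Z975 = 1.959964
I2_GATE = 0.4
MASK_THRESHOLD = 5


@dataclass(frozen=True)
class MetaResult:
    pooled_log_hr: float | None
    pooled_se: float | None
    pooled_hr: float | None
    ci95_low: float | None
    ci95_high: float | None
    p_two_sided: float | None
    Q: float
    df: int
    i_squared: float
    tau_squared: float
    gated: bool
    n_databases: int


@dataclass(frozen=True)
class MaskedCount:
    raw: int
    display: str


def heterogeneity(
    estimates: list[tuple[float, float]] | np.ndarray,
) -> tuple[float, int, float, float, bool]:
    """Cochran's Q, I^2 and the DerSimonian-Laird tau^2 for a set of estimates.

    ``estimates`` is a sequence of (log_hr, se) pairs.  With a single
    estimate there is nothing to compare: Q = 0, I^2 = 0, not gated.
    Returns ``(Q, df, i_squared, tau_squared, gated)`` with
    ``gated = (i_squared >= 0.4)``.
    """
    arr = np.asarray(estimates, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("estimates must be (log_hr, se) pairs")
    theta, se = arr[:, 0], arr[:, 1]
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    k = len(theta)
    if k == 1:
        return 0.0, 0, 0.0, 0.0, False
    w = 1.0 / se**2
    theta_fixed = float(np.sum(w * theta) / np.sum(w))
    Q = float(np.sum(w * (theta - theta_fixed) ** 2))
    df = k - 1
    i2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
    return Q, df, float(i2), float(tau2), bool(i2 >= I2_GATE)


def random_effects_pool(
    estimates: list[tuple[float, float]] | np.ndarray,
    tau_squared: float,
) -> MetaResult:
    """Inverse-variance pooling with between-database variance added.

    Weights are ``1 / (se_i^2 + tau^2)``; with ``tau^2 = 0`` this is exactly
    the fixed-effects estimate.  Must not be called on a gated estimate set
    (checked; raises).  A single estimate passes through unchanged.
    """
    arr = np.asarray(estimates, dtype=float)
    Q, df, i2, _, gated = heterogeneity(arr)
    if gated:
        raise ValueError(
            f"estimate set is gated (I^2 = {i2:.2f} >= {I2_GATE}); no pooled estimate may be produced"
        )
    theta, se = arr[:, 0], arr[:, 1]
    w = 1.0 / (se**2 + tau_squared)
    pooled = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    return MetaResult(
        pooled_log_hr=pooled,
        pooled_se=pooled_se,
        pooled_hr=float(np.exp(pooled)),
        ci95_low=float(np.exp(pooled - Z975 * pooled_se)),
        ci95_high=float(np.exp(pooled + Z975 * pooled_se)),
        p_two_sided=float(2 * stats.norm.sf(abs(pooled / pooled_se))),
        Q=Q,
        df=df,
        i_squared=i2,
        tau_squared=float(tau_squared),
        gated=False,
        n_databases=len(theta),
    )


def meta_analysis(estimates: list[tuple[float, float]] | np.ndarray) -> MetaResult:
    """Heterogeneity assessment plus (unless gated) the DL pooled estimate."""
    Q, df, i2, tau2, gated = heterogeneity(estimates)
    if gated:
        return MetaResult(
            pooled_log_hr=None, pooled_se=None, pooled_hr=None,
            ci95_low=None, ci95_high=None, p_two_sided=None,
            Q=Q, df=df, i_squared=i2, tau_squared=tau2, gated=True,
            n_databases=len(np.asarray(estimates)),
        )
    return random_effects_pool(estimates, tau2)


def pool_counts_and_rates(per_database: pd.DataFrame) -> dict:
    """Totals row for a multi-database counts table.

    ``per_database`` needs columns ``users_target, users_comparator,
    events_target, events_comparator, rate_target, rate_comparator`` (rates
    per 1000 person-years) and optionally ``persontime_target/_comparator``
    in person-years.  User and event totals are sums; the pooled rate is
    total events over total person-time, with person-time back-derived as
    ``events / rate`` (in thousands of person-years) wherever raw
    person-time is absent.
    """
    df = per_database
    out = {}
    for arm in ("target", "comparator"):
        events = df[f"events_{arm}"].to_numpy(dtype=float)
        rates = df[f"rate_{arm}"].to_numpy(dtype=float)
        if np.any((events > 0) & (rates <= 0)):
            raise ValueError(f"events > 0 with rate 0 in arm {arm}")
        if f"persontime_{arm}" in df.columns:
            pt = df[f"persontime_{arm}"].to_numpy(dtype=float) / 1000.0
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                pt = np.where(rates > 0, events / rates, 0.0)
        out[f"users_{arm}"] = int(df[f"users_{arm}"].sum())
        out[f"events_{arm}"] = int(events.sum())
        out[f"rate_{arm}"] = float(events.sum() / pt.sum()) if pt.sum() > 0 else 0.0
    return out


def mask_small_counts(raw: int, threshold: int = MASK_THRESHOLD) -> MaskedCount:
    """Privacy masking: counts in [1, threshold) display as "<threshold".

    Zero is displayed as "0" (zero-event analyses are excluded upstream, so
    a zero is structural, not a small cell).
    """
    if raw < 0:
        raise ValueError("count must be non-negative")
    if 1 <= raw < threshold:
        return MaskedCount(raw=raw, display=f"<{threshold}")
    return MaskedCount(raw=raw, display=str(raw))


def mask_rate(
    events: int, person_years: float, threshold: int = MASK_THRESHOLD, decimals: int = 2
) -> str:
    """Incidence rate display honouring count masking.

    A rate computed from a masked event count cannot be shown exactly; it is
    rendered as the upper bound implied by the threshold:
    ``"<" + threshold / person_years * 1000``.
    """
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    masked = mask_small_counts(events, threshold)
    if masked.display.startswith("<"):
        bound = threshold / person_years * 1000.0
        return f"<{bound:.{decimals}f}"
    return f"{events / person_years * 1000.0:.{decimals}f}"


def forest_data(
    per_database: pd.DataFrame,
    meta: MetaResult,
    label_col: str = "database",
) -> pd.DataFrame:
    """Forest-plot table: one row per database plus a pooled row unless gated.

    ``per_database`` needs ``database, hr, ci95_low, ci95_high`` columns
    (calibrated values in practice).
    """
    rows = per_database[[label_col, "hr", "ci95_low", "ci95_high"]].copy()
    rows["pooled"] = False
    if not meta.gated:
        pooled = pd.DataFrame(
            [
                {
                    label_col: "Meta-analysis",
                    "hr": meta.pooled_hr,
                    "ci95_low": meta.ci95_low,
                    "ci95_high": meta.ci95_high,
                    "pooled": True,
                }
            ]
        )
        rows = pd.concat([rows, pooled], ignore_index=True)
    return rows
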