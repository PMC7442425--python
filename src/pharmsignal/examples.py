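"""Worked multi-database summary rows used in documentation and tests.

Illustrative per-database patient counts, event counts and incidence rates
(per 1000 person-years) for the hydroxychloroquine-safety setting this
package targets: hydroxychloroquine (HCQ) vs sulfasalazine (SSZ) new users,
and HCQ+azithromycin vs HCQ+amoxicillin, for cardiovascular mortality.
They exercise the pooled-row arithmetic (count sums, person-time-weighted
pooled rates, small-cell masking) exactly as a reporting pipeline would.

Rates for masked cells (events below 5) are the "<" upper bounds implied by
the masking threshold; the underlying person-time is recovered from the
bound as ``threshold / bound``.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "cv_mortality_itt_hcq_ssz",
    "cv_mortality_ontreatment_hcq_ssz",
    "cv_mortality_itt_combination",
]


def cv_mortality_itt_hcq_ssz() -> pd.DataFrame:
    """Cardiovascular mortality, 30-day intention-to-treat, HCQ vs SSZ.

    Comparator event cells are masked small cells (<5); their rate columns
    hold the masked upper bound, so pooled comparator rates are bounds too.
    """
    return pd.DataFrame(
        [
            {
                "database": "Clinformatics",
                "users_target": 51280, "users_comparator": 17389,
                "events_target": 16, "events_comparator": 5,
                "rate_target": 3.85, "rate_comparator": 3.54,
                "comparator_masked": True,
            },
            {
                "database": "VA",
                "users_target": 32028, "users_comparator": 14349,
                "events_target": 9, "events_comparator": 5,
                "rate_target": 3.43, "rate_comparator": 4.25,
                "comparator_masked": True,
            },
        ]
    )


def cv_mortality_ontreatment_hcq_ssz() -> pd.DataFrame:
    """Cardiovascular mortality, on-treatment follow-up, HCQ vs SSZ."""
    return pd.DataFrame(
        [
            {
                "database": "Clinformatics",
                "users_target": 51280, "users_comparator": 17389,
                "events_target": 234, "events_comparator": 25,
                "rate_target": 4.39, "rate_comparator": 2.00,
            },
            {
                "database": "CPRD",
                "users_target": 9127, "users_comparator": 11398,
                "events_target": 7, "events_comparator": 25,
                "rate_target": 0.39, "rate_comparator": 0.94,
            },
            {
                "database": "VA",
                "users_target": 32028, "users_comparator": 14349,
                "events_target": 315, "events_comparator": 65,
                "rate_target": 5.69, "rate_comparator": 3.71,
            },
        ]
    )


def cv_mortality_itt_combination() -> pd.DataFrame:
    """Cardiovascular mortality, 30-day ITT, HCQ+azithromycin vs HCQ+amoxicillin."""
    return pd.DataFrame(
        [
            {
                "database": "Clinformatics",
                "users_target": 23597, "users_comparator": 24521,
                "events_target": 9, "events_comparator": 6,
                "rate_target": 4.70, "rate_comparator": 3.02,
            },
            {
                "database": "VA",
                "users_target": 6234, "users_comparator": 8005,
                "events_target": 46, "events_comparator": 18,
                "rate_target": 90.60, "rate_comparator": 27.49,
            },
        ]
    )
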