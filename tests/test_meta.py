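"""Heterogeneity gating, DerSimonian-Laird pooling, count pooling, masking."""

import numpy as np
import pandas as pd
import pytest

import pharmsignal as ps
from pharmsignal import examples

# Independent reference values computed with R metafor (rma, method="DL")
# for the toy triple theta = (0.1, 0.3, 0.5), se = 0.2 each.
METAFOR_TRIPLE = {
    "b": 0.300000000000000,
    "se": 0.115470053837925,
    "tau2": 0.0,
    "Q": 2.0,
    "ci_lb": 0.073682853184766,
    "ci_ub": 0.526317146815234,
}


class TestHeterogeneity:
    def test_identical_estimates_no_heterogeneity(self):
        Q, df, i2, tau2, gated = ps.heterogeneity([(0.2, 0.1)] * 4)
        assert Q == pytest.approx(0.0, abs=1e-12)
        assert i2 == 0 and tau2 == pytest.approx(0.0, abs=1e-12) and not gated

    def test_hand_computed_toy(self):
        """theta = (0, 1), se = (0.5, 0.5): w = (4, 4), fixed mean 0.5,
        Q = 2, I2 = 0.5, tau2 = (Q - df) / (sum w - sum w^2 / sum w) = 0.25."""
        Q, df, i2, tau2, gated = ps.heterogeneity([(0.0, 0.5), (1.0, 0.5)])
        assert Q == pytest.approx(2.0)
        assert df == 1
        assert i2 == pytest.approx(0.5)
        assert tau2 == pytest.approx(0.25)
        assert gated

    def test_single_estimate_passes_through(self):
        Q, df, i2, tau2, gated = ps.heterogeneity([(0.3, 0.2)])
        assert (Q, df, i2, tau2, gated) == (0.0, 0, 0.0, 0.0, False)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            ps.heterogeneity([(0.1, 0.0), (0.2, 0.1)])

    def test_i2_invariant_under_constant_shift(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            theta = rng.normal(0, 0.5, 6)
            se = rng.uniform(0.1, 0.4, 6)
            base = ps.heterogeneity(list(zip(theta, se)))
            shifted = ps.heterogeneity(list(zip(theta + 1.7, se)))
            assert shifted[2] == pytest.approx(base[2])
            assert shifted[0] == pytest.approx(base[0])


class TestRandomEffectsPool:
    def test_single_estimate_identity(self):
        m = ps.meta_analysis([(0.4, 0.25)])
        assert m.pooled_log_hr == pytest.approx(0.4)
        assert m.pooled_se == pytest.approx(0.25)

    def test_identical_estimates_shrink_se_by_sqrt_k(self):
        m = ps.random_effects_pool([(0.2, 0.3)] * 4, tau_squared=0.0)
        assert m.pooled_log_hr == pytest.approx(0.2)
        assert m.pooled_se == pytest.approx(0.3 / 2)

    def test_tau_zero_equals_fixed_effects(self):
        theta = np.array([0.1, 0.25, 0.4])
        se = np.array([0.2, 0.15, 0.3])
        m = ps.random_effects_pool(list(zip(theta, se)), tau_squared=0.0)
        w = 1 / se**2
        assert m.pooled_log_hr == pytest.approx(float(np.sum(w * theta) / np.sum(w)), abs=1e-12)

    def test_matches_metafor_reference(self):
        m = ps.meta_analysis([(0.1, 0.2), (0.3, 0.2), (0.5, 0.2)])
        assert m.pooled_log_hr == pytest.approx(METAFOR_TRIPLE["b"], abs=1e-10)
        assert m.pooled_se == pytest.approx(METAFOR_TRIPLE["se"], abs=1e-10)
        assert m.tau_squared == pytest.approx(METAFOR_TRIPLE["tau2"], abs=1e-10)
        assert m.Q == pytest.approx(METAFOR_TRIPLE["Q"], abs=1e-10)
        assert np.log(m.ci95_low) == pytest.approx(METAFOR_TRIPLE["ci_lb"], abs=1e-6)
        assert np.log(m.ci95_high) == pytest.approx(METAFOR_TRIPLE["ci_ub"], abs=1e-6)

    def test_gated_set_refused(self):
        gated_set = [(0.0, 0.5), (1.0, 0.5)]
        with pytest.raises(ValueError):
            ps.random_effects_pool(gated_set, tau_squared=0.25)

    def test_gate_withholds_pooled_estimate(self):
        m = ps.meta_analysis([(0.0, 0.5), (1.0, 0.5)])
        assert m.gated
        assert m.pooled_hr is None and m.pooled_log_hr is None


class TestPooledCounts:
    def test_user_totals(self):
        row = ps.pool_counts_and_rates(examples.cv_mortality_itt_hcq_ssz())
        assert row["users_target"] == 83_308
        assert row["events_target"] == 25

    def test_event_sum_on_treatment(self):
        row = ps.pool_counts_and_rates(examples.cv_mortality_ontreatment_hcq_ssz())
        assert row["users_target"] == 92_435
        assert row["events_target"] == 234 + 7 + 315 == 556
        assert row["rate_target"] == pytest.approx(4.39, abs=0.005)

    def test_persontime_weighted_pooled_rate(self):
        """(9 events at 4.70) + (46 events at 90.60) pools to 22.70 per
        1000 person-years, not the naive average of the two rates."""
        row = ps.pool_counts_and_rates(examples.cv_mortality_itt_combination())
        assert row["rate_target"] == pytest.approx(22.70, abs=0.005)
        assert row["users_target"] == 29_831

    def test_order_invariance(self):
        df = examples.cv_mortality_ontreatment_hcq_ssz()
        a = ps.pool_counts_and_rates(df)
        b = ps.pool_counts_and_rates(df.iloc[::-1].reset_index(drop=True))
        assert a == b

    def test_events_without_rate_rejected(self):
        df = examples.cv_mortality_itt_combination().copy()
        df.loc[0, "rate_target"] = 0.0
        with pytest.raises(ValueError):
            ps.pool_counts_and_rates(df)

    def test_explicit_persontime_used_when_given(self):
        df = pd.DataFrame(
            [
                {"users_target": 10, "users_comparator": 10, "events_target": 5,
                 "events_comparator": 2, "rate_target": 999.0, "rate_comparator": 999.0,
                 "persontime_target": 1000.0, "persontime_comparator": 500.0},
            ]
        )
        row = ps.pool_counts_and_rates(df)
        assert row["rate_target"] == pytest.approx(5.0)
        assert row["rate_comparator"] == pytest.approx(4.0)


class TestMasking:
    @pytest.mark.parametrize("raw, display", [(0, "0"), (1, "<5"), (3, "<5"), (4, "<5"), (5, "5"), (17, "17")])
    def test_display_dialect(self, raw, display):
        assert ps.mask_small_counts(raw).display == display
        assert ps.mask_small_counts(raw).raw == raw

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ps.mask_small_counts(-1)

    def test_masked_rate_renders_upper_bound(self):
        """A masked event count turns the rate into the bound implied by
        the masking threshold: 5 events over 1412.43 person-years -> <3.54."""
        assert ps.mask_rate(3, 5 / 3.54 * 1000.0) == "<3.54"
        assert ps.mask_rate(16, 16 / 3.85 * 1000.0) == "3.85"


class TestForestData:
    def _per_db(self):
        return pd.DataFrame(
            {
                "database": ["A", "B", "C"],
                "hr": [1.1, 1.3, 0.9],
                "ci95_low": [0.8, 0.9, 0.6],
                "ci95_high": [1.5, 1.9, 1.4],
            }
        )

    def test_pooled_row_present_when_not_gated(self):
        m = ps.meta_analysis([(0.1, 0.2), (0.26, 0.2), (-0.1, 0.2)])
        fd = ps.meta.forest_data(self._per_db(), m)
        assert len(fd) == 4 and fd["pooled"].sum() == 1
        assert fd.iloc[-1]["database"] == "Meta-analysis"

    def test_no_pooled_row_when_gated(self):
        m = ps.meta_analysis([(0.0, 0.5), (1.0, 0.5)])
        fd = ps.meta.forest_data(self._per_db().iloc[:2], m)
        assert len(fd) == 2 and fd["pooled"].sum() == 0
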