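"""Stop-rule engine and glipizide endpoint derivations: threshold logic,
trough/peak search, trapezoid areas, residual adjustment, censoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import sugarkit as sk
from sugarkit.glipizide import (
    REASON_ABSOLUTE,
    REASON_COMPLETED,
    REASON_NEURO,
    REASON_NOT_DOSED,
    REASON_SYMPTOMATIC,
)


class TestStopRules:
    def test_no_threshold_crossed_completes_at_240(self, make_glip_series):
        s = make_glip_series([5.0, 4.0, 3.5, 3.0, 3.2, 3.6, 4.1])
        out, term, reason = sk.apply_stop_rules(s)
        assert (term, reason) == (240, REASON_COMPLETED)
        assert out.n_times == 7

    def test_absolute_threshold_terminates_inclusive(self, make_glip_series):
        s = make_glip_series([5.0, 4.0, 3.0, 2.4, 3.0, 3.5, 4.0])
        out, term, reason = sk.apply_stop_rules(s)
        assert (term, reason) == (90, REASON_ABSOLUTE)
        assert list(out.times) == [0, 30, 60, 90]

    def test_baseline_below_gate_is_not_dosed(self, make_glip_series):
        s = make_glip_series([4.3, 4.0, 3.8])
        _, term, reason = sk.apply_stop_rules(s)
        assert term is None and reason == REASON_NOT_DOSED

    # hand-enumerated rule table: (glucose, hypoglycemic symptom,
    # neuroglycopenic symptom) -> (terminates, reason).  Rule priority is
    # neuroglycopenia, then symptomatic <= 2.77, then absolute < 2.50; the
    # symptomatic bound is inclusive, the absolute bound exclusive.
    TRUTH_TABLE = [
        (3.50, False, False, None),
        (3.50, True, False, None),
        (3.50, False, True, REASON_NEURO),
        (2.90, True, False, None),
        (2.77, False, False, None),
        (2.77, True, False, REASON_SYMPTOMATIC),
        (2.77, True, True, REASON_NEURO),
        (2.60, False, False, None),
        (2.60, True, False, REASON_SYMPTOMATIC),
        (2.50, False, False, None),
        (2.50, True, False, REASON_SYMPTOMATIC),
        (2.49, False, False, REASON_ABSOLUTE),
        (2.49, True, False, REASON_SYMPTOMATIC),
        (2.49, False, True, REASON_NEURO),
    ]

    @pytest.mark.parametrize("glucose,hypo,neuro,expected", TRUTH_TABLE)
    def test_rule_truth_table(self, make_glip_series, glucose, hypo, neuro, expected):
        s = make_glip_series(
            [5.0, glucose, 3.5, 3.5, 3.5, 3.5, 3.5],
            hypo=[False, hypo, False, False, False, False, False],
            neuro=[False, neuro, False, False, False, False, False],
        )
        _, term, reason = sk.apply_stop_rules(s)
        if expected is None:
            assert (term, reason) == (240, REASON_COMPLETED)
        else:
            assert (term, reason) == (30, expected)

    def test_engine_is_idempotent(self, make_glip_series):
        s = make_glip_series([5.0, 3.1, 2.6, 2.3, 3.0, 3.5, 4.0],
                             hypo=[False, False, True, False, False, False, False])
        once, term1, reason1 = sk.apply_stop_rules(s)
        twice, term2, reason2 = sk.apply_stop_rules(once)
        assert (term1, reason1) == (term2, reason2) == (60, REASON_SYMPTOMATIC)
        np.testing.assert_array_equal(once.times, twice.times)
        np.testing.assert_allclose(once.glucose, twice.glucose)


class TestTroughAndPeak:
    def test_trough_tie_breaks_to_earliest(self, make_glip_series):
        s = make_glip_series([5.0, 3.0, 3.0], times=(0, 60, 120))
        assert sk.glucose_trough(s) == (3.0, 60)

    def test_trough_of_monotone_decline_sits_at_termination(self, make_glip_series):
        s = make_glip_series([5.0, 4.0, 3.0, 2.4], times=(0, 30, 60, 90))
        assert sk.glucose_trough(s) == (2.4, 90)

    def test_baseline_excluded_from_trough_search(self, make_glip_series):
        s = make_glip_series([3.0, 3.5, 4.0], times=(0, 60, 120))
        assert sk.glucose_trough(s) == (3.5, 60)

    def test_insulin_peak_skips_gaps_and_breaks_ties_early(self, make_glip_series):
        s = make_glip_series([5.0, 4.0, 3.5], times=(0, 60, 120),
                             insulin=[30.0, np.nan, 200.0])
        assert sk.insulin_peak(s) == (200.0, 120)
        s = make_glip_series([5.0, 4.0, 3.5], times=(0, 60, 120),
                             insulin=[30.0, 150.0, 150.0])
        assert sk.insulin_peak(s) == (150.0, 60)

    def test_no_post_baseline_insulin_means_absent(self, make_glip_series):
        s = make_glip_series([5.0, 4.0], times=(0, 60),
                             insulin=[30.0, np.nan])
        assert sk.insulin_peak(s) is None


class TestAreas:
    def test_constant_curve_has_zero_adjusted_area(self, make_glip_series):
        s = make_glip_series([4.0] * 7)
        assert sk.auc_trapezoid(s, "glucose", 0, 240, baseline_adjust=True) == 0.0
        assert sk.aoc_glucose(s, 240) == 0.0

    def test_hand_computed_trapezoid(self, make_glip_series):
        s = make_glip_series([5.0, 4.0, 3.0], times=(0, 60, 120))
        assert sk.auc_trapezoid(s, "glucose", 0, 120) == pytest.approx(480.0)

    def test_linear_decline_aoc_closed_form(self, make_glip_series):
        # glucose falls linearly B -> B - d over [0, T]: AOC = d*T/2
        B, d, T = 5.0, 2.0, 240
        times = np.array([0, 30, 60, 90, 120, 180, 240])
        s = make_glip_series(B - d * times / T, times=tuple(times))
        assert sk.aoc_glucose(s, T) == pytest.approx(d * T / 2)

    def test_trapezoid_matches_independent_quadrature(self, make_glip_series):
        rng = np.random.default_rng(8)
        times = np.array([0, 30, 60, 90, 120, 180, 240])
        glucose = rng.uniform(2.5, 9.0, times.size)
        s = make_glip_series(glucose, times=tuple(times))
        oracle, _ = integrate.quad(
            lambda t: np.interp(t, times, glucose), 0, 240, limit=200
        )
        assert sk.auc_trapezoid(s, "glucose", 0, 240) == pytest.approx(
            oracle, rel=1e-9
        )

    def test_range_beyond_truncated_series_is_absent(self, make_glip_series):
        s = make_glip_series([5.0, 4.0, 3.0], times=(0, 30, 60),
                             insulin=[30.0, 100.0, 200.0])
        assert sk.auc_trapezoid(s, "insulin", 0, 240) is None
        assert sk.auc_trapezoid(s, "glucose", 0, 120) is None

    def test_interior_gap_makes_area_absent(self, make_glip_series):
        s = make_glip_series([5.0, 4.0, 3.0], times=(0, 60, 120),
                             insulin=[30.0, np.nan, 200.0])
        assert sk.auc_trapezoid(s, "insulin", 0, 120) is None

    @given(
        st.lists(st.floats(min_value=0.5, max_value=25.0), min_size=2, max_size=7)
    )
    @settings(derandomize=True, max_examples=100)
    def test_aoc_plus_auc_equals_baseline_times_t(self, glucose):
        times = (0, 30, 60, 90, 120, 180, 240)[: len(glucose)]
        s = sk.ChallengeSeries("p", "glipizide", np.array(times),
                               np.array(glucose))
        t_end = times[-1]
        auc = sk.auc_trapezoid(s, "glucose", 0, t_end)
        aoc = sk.aoc_glucose(s, t_end)
        assert aoc + auc == pytest.approx(glucose[0] * t_end, rel=1e-9)


class TestCounterRegSlope:
    def test_slope_arithmetic(self, make_glip_series, completer):
        s = make_glip_series([5.0, 4.5, 4.0, 3.5, 3.0, 3.6, 4.2])
        assert sk.counter_reg_slope(s, completer) == pytest.approx(
            (4.2 - 3.0) / (240 - 120)
        )

    def test_rescued_participants_excluded(self, make_glip_series):
        p = sk.ParticipantRecord("p1", 50.0, "female", "other", 30.0,
                                 received_glipizide=True, termination_time=90,
                                 rescued=True)
        s = make_glip_series([5.0, 3.0, 2.6, 2.3], times=(0, 30, 60, 90))
        assert sk.counter_reg_slope(s, p) is None

    def test_trough_at_240_has_no_slope(self, make_glip_series, completer):
        s = make_glip_series([5.0, 4.5, 4.4, 4.3, 4.2, 4.1, 4.0])
        assert sk.counter_reg_slope(s, completer) is None


class TestResidualAdjust:
    def test_exactly_linear_endpoint_gives_zero_residuals(self):
        cov = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        y = 2.0 + 0.5 * cov
        np.testing.assert_allclose(sk.residual_adjust(y, cov), 0.0, atol=1e-12)

    def test_normal_equations_hold(self):
        rng = np.random.default_rng(0)
        cov = pd.Series(rng.normal(5, 1, 50))
        y = pd.Series(1.0 + 0.3 * cov + rng.normal(0, 0.5, 50))
        r = sk.residual_adjust(y, cov)
        assert abs(r.mean()) < 1e-9
        assert abs(np.dot(r, cov - cov.mean())) < 1e-7

    def test_uncorrelated_covariate_leaves_variance(self):
        rng = np.random.default_rng(1)
        n = 4000
        y = pd.Series(rng.normal(0, 2.0, n))
        cov = pd.Series(rng.normal(0, 1.0, n))
        r = sk.residual_adjust(y, cov)
        assert r.var() == pytest.approx(y.var(), rel=0.05)

    def test_missing_values_excluded_pairwise(self):
        y = pd.Series([1.0, np.nan, 3.0, 4.0, 5.0])
        cov = pd.Series([1.0, 2.0, np.nan, 4.0, 5.0])
        r = sk.residual_adjust(y, cov)
        assert list(r.index) == [0, 3, 4]

    def test_zero_covariate_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            sk.residual_adjust(pd.Series([1.0, 2.0, 3.0]),
                               pd.Series([2.0, 2.0, 2.0]))


class TestEndpointDerivation:
    def test_full_series_yields_all_raw_endpoints(self, make_glip_series, completer):
        s = make_glip_series([5.0, 4.2, 3.6, 3.2, 3.0, 3.4, 4.0],
                             insulin=[30, 150, 320, 250, 180, 100, 60])
        ep = sk.derive_glipizide_endpoints(s, completer)
        assert all(v is not None for v in ep.values())
        assert ep["glucose_trough"] == 3.0
        assert ep["time_to_glucose_trough"] == 120
        assert ep["insulin_peak"] == 320
        assert ep["time_to_insulin_peak"] == 60
        assert ep["delta_glucose_0_to_trough"] == pytest.approx(-2.0)
        assert ep["rate_to_trough"] == pytest.approx(-2.0 / 120)

    def test_sixty_minute_terminator_censors_later_endpoints(self, make_glip_series):
        p = sk.ParticipantRecord("p1", 50.0, "male", "other", 30.0,
                                 received_glipizide=True, termination_time=60,
                                 rescued=True)
        s = make_glip_series([5.0, 3.0, 2.4], times=(0, 30, 60),
                             insulin=[30, 150, 300])
        ep = sk.derive_glipizide_endpoints(s, p)
        for name in ("delta_glucose_0_to_90", "delta_glucose_0_to_120",
                     "glucose_at_120", "aoc_glucose_0_120", "auc_insulin_0_240",
                     "counter_reg_slope", "delta_glucose_trough_to_240"):
            assert ep[name] is None, name
        assert ep["glucose_trough"] == 2.4

    def test_undosed_participant_rejected(self, make_glip_series):
        p = sk.ParticipantRecord("p1", 50.0, "male", "other", 30.0)
        s = make_glip_series([5.0, 4.0, 3.5], times=(0, 30, 60))
        with pytest.raises(ValueError):
            sk.derive_glipizide_endpoints(s, p)

    def test_cohort_residual_columns_centered_and_tagged(self, default_cohort):
        table = sk.derive_glipizide_cohort(
            default_cohort.series, default_cohort.participants
        )
        for name in sk.glipizide.SELECTED_GLIPIZIDE_ENDPOINTS:
            assert name in table.values.columns or name == "counter_reg_slope"
        col = table.values["glucose_trough_adj_baseline_glucose"].dropna()
        assert abs(col.mean()) < 1e-9 * max(1.0, col.abs().max())
        assert table.provenance["glucose_trough_adj_baseline_glucose"] == \
            "residual_adjusted"
        assert table.provenance["glucose_trough"] == "raw"


class TestTerminationSummary:
    def test_counts_and_percentages(self):
        participants = []
        for i, t in enumerate([60] * 2 + [90] * 3 + [240] * 5):
            participants.append(
                sk.ParticipantRecord(f"p{i}", 40.0, "male", "other", 30.0,
                                     received_glipizide=True, termination_time=t,
                                     rescued=t < 240)
            )
        participants.append(
            sk.ParticipantRecord("nd", 40.0, "male", "other", 30.0)
        )
        rep = sk.termination_summary(participants)
        assert rep.loc["challenged", "n"] == 10
        assert rep.loc["early_terminators", "n"] == 5
        assert rep.loc["early_terminators", "pct"] == 50.0
        assert rep.loc["terminated_90", "n"] == 3
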