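"""Recovery value flip detection: hand-traced examples, eligibility
statuses, decline rates, site summaries and detector behaviour on the
kinetic simulator with and without reading noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ZERO_NOISE, series_from_course, series_from_deltas
from srbvkit.kinetics import (
    NeonateProfile,
    NoiseModel,
    default_kinetics,
    simulate_course,
)
from srbvkit.rvp import (
    MIN_ADEQUATE_CYCLES,
    RVP_BASELINE_ELIGIBILITY,
    CourseSeries,
    compute_deltas,
    decline_rate,
    detect_rvp,
    series_from_measurements,
    summarise_site,
)


class TestComputeDeltas:
    def test_delta_is_return_minus_out(self):
        s = series_from_deltas([0.3, -0.2])
        assert compute_deltas(s) == pytest.approx([0.3, -0.2])

    def test_empty_series_rejected(self):
        s = CourseSeries("n", "A", 14.0, ())
        with pytest.raises(ValueError):
            compute_deltas(s)


class TestDetectRvp:
    def test_hand_trace_flip_at_three(self):
        # deltas + + - - - : flip at the first negative that opens a run
        r = detect_rvp(series_from_deltas([0.4, 0.2, -0.1, -0.2, -0.2]))
        assert r.status == "rvp_detected"
        assert r.rvp_cycle == 3

    def test_single_negative_excursion_is_not_a_flip(self):
        # deltas + - + + + : one isolated negative, no run, no terminal
        r = detect_rvp(series_from_deltas([0.4, -0.1, 0.2, 0.1, 0.1]))
        assert r.status == "no_flip"
        assert r.rvp_cycle is None

    def test_excursion_then_real_flip(self):
        # + - + - - : the isolated dip at 2 is skipped; flip at 4
        r = detect_rvp(series_from_deltas([0.4, -0.1, 0.2, -0.1, -0.2]))
        assert r.status == "rvp_detected"
        assert r.rvp_cycle == 4

    def test_terminal_negative_counts_without_confirmation(self):
        r = detect_rvp(series_from_deltas([0.3, 0.1, -0.1]))
        assert r.status == "rvp_detected"
        assert r.rvp_cycle == 3

    def test_zero_delta_counts_as_pre_flip(self):
        r = detect_rvp(series_from_deltas([0.3, 0.0, -0.1, -0.1]))
        assert r.status == "rvp_detected"
        assert r.rvp_cycle == 3

    def test_all_negative_is_immediate_decline(self):
        r = detect_rvp(series_from_deltas([-0.1, -0.2, -0.1]))
        assert r.status == "immediate_decline"

    def test_low_baseline_is_ineligible(self):
        s = series_from_deltas([0.3, -0.1, -0.1], baseline=RVP_BASELINE_ELIGIBILITY)
        assert detect_rvp(s).status == "ineligible_low_baseline"
        just_above = series_from_deltas(
            [0.3, -0.1, -0.1], baseline=RVP_BASELINE_ELIGIBILITY + 0.1
        )
        assert detect_rvp(just_above).status == "rvp_detected"

    def test_short_series_is_insufficient(self):
        s = series_from_deltas([0.3, -0.1][: MIN_ADEQUATE_CYCLES - 1])
        assert detect_rvp(s).status == "insufficient_data"

    def test_monotone_flag_reflects_out_readings(self):
        declining = detect_rvp(series_from_deltas([0.3, 0.1, -0.1, -0.1], step=-0.5))
        assert declining.post_rvp_monotone
        rising = detect_rvp(series_from_deltas([0.3, 0.1, -0.1, -0.1], step=0.2))
        assert not rising.post_rvp_monotone

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            # zero or clearly signed: deltas below float round-off against
            # a ~13 mg/dL reading cannot survive the series construction
            st.one_of(
                st.just(0.0),
                st.floats(min_value=1e-3, max_value=0.5),
                st.floats(min_value=-0.5, max_value=-1e-3),
            ),
            min_size=3,
            max_size=9,
        )
    )
    def test_detected_cycle_is_a_genuine_sign_change(self, deltas):
        """Whenever a flip is detected, the predecessor delta is
        non-negative and the flip delta negative; detection is invariant
        to a uniform positive rescaling of all deltas."""
        r = detect_rvp(series_from_deltas(deltas))
        if r.status == "rvp_detected":
            j = r.rvp_cycle
            assert deltas[j - 2] >= 0 and deltas[j - 1] < 0
        scaled = detect_rvp(series_from_deltas([3.0 * d for d in deltas]))
        assert scaled.status == r.status
        assert scaled.rvp_cycle == r.rvp_cycle


class TestDeclineRate:
    def test_linear_decline_recovered_exactly(self):
        # outs drop 0.5 mg/dL per 10/3 h cycle -> 0.15 mg/dL/h
        s = series_from_deltas([0.0] * 4, start_out=13.0, step=-0.5)
        assert decline_rate(s) == pytest.approx(0.5 / (10.0 / 3.0))

    def test_flat_series_rate_zero(self):
        s = series_from_deltas([0.0] * 4, step=0.0)
        assert decline_rate(s) == pytest.approx(0.0, abs=1e-12)

    def test_endpoint_method_two_point_slope(self):
        s = series_from_deltas([0.0] * 2, start_out=13.0, step=-0.5)
        # 0.5 mg/dL over one cycle spacing of 10/3 h
        assert decline_rate(s, method="endpoint") == pytest.approx(0.15)

    def test_rise_comes_back_negative(self):
        s = series_from_deltas([0.0] * 3, step=+0.5)
        assert decline_rate(s) < 0

    def test_single_cycle_rejected(self):
        s = series_from_deltas([0.1])
        with pytest.raises(ValueError):
            decline_rate(s)


class TestSummariseSite:
    def test_counts_and_percentage(self):
        series = [
            series_from_deltas([0.3, 0.1, -0.1, -0.1]),  # detected
            series_from_deltas([0.3, 0.2, 0.1, 0.1]),  # no flip
            series_from_deltas([0.3, -0.1, -0.1], baseline=8.0),  # ineligible
        ]
        # distinct ids required for the lookup
        series = [
            CourseSeries(f"n{i}", s.site_id, s.baseline_tbl, s.cycles)
            for i, s in enumerate(series)
        ]
        results = [detect_rvp(s) for s in series]
        summ = summarise_site(series, results)
        assert summ.n_patients == 3
        assert summ.n_eligible == 2
        assert summ.rvp_observed_pct == pytest.approx(50.0)
        assert summ.tbl_range == (8.0, 14.0)

    def test_mixed_sites_rejected(self):
        a = series_from_deltas([0.1, -0.1, -0.1])
        b = CourseSeries("x", "OTHER", 14.0, a.cycles)
        with pytest.raises(ValueError, match="multiple sites"):
            summarise_site([a, b], [detect_rvp(a), detect_rvp(b)])

    def test_ages_summarised_when_given(self):
        s = series_from_deltas([0.1, -0.1, -0.1])
        summ = summarise_site([s], [detect_rvp(s)], ages_days=[4.0])
        assert summ.mean_age_days == pytest.approx(4.0)
        assert summ.sd_age_days == 0.0


class TestOnSimulator:
    def test_noise_free_default_course_flips_at_cycle_three(self, schedule):
        """The frozen generator defaults place the flip at cycle 3 for a
        composite baseline near 13 mg/dL."""
        prof = NeonateProfile("n", "s", 4.0, 11.2, default_kinetics(11.2))
        course = simulate_course(prof, schedule, ZERO_NOISE)
        r = detect_rvp(series_from_course(course, schedule))
        assert r.status == "rvp_detected"
        assert r.rvp_cycle == 3
        assert r.post_rvp_monotone

    def test_flip_cycle_noise_robustness_at_small_cv(self, schedule):
        """With reading noise small relative to the rebound scale
        (cv 0.002), the detected flip lands within +/-1 cycle of the
        noise-free flip in at least 90% of replicates."""
        prof = NeonateProfile("n", "s", 4.0, 11.2, default_kinetics(11.2))
        ref = detect_rvp(
            series_from_course(simulate_course(prof, schedule, ZERO_NOISE), schedule)
        )
        assert ref.status == "rvp_detected"
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            noise = NoiseModel(tcb_cv=0.002, tsb_cv=0.0, seed=10_000 + seed)
            course = simulate_course(prof, schedule, noise)
            r = detect_rvp(series_from_course(course, schedule))
            if r.status == "rvp_detected" and abs(r.rvp_cycle - ref.rvp_cycle) <= 1:
                hits += 1
        assert hits / n_rep >= 0.90

    def test_decline_rate_matches_trajectory_finite_difference(self, schedule):
        """The endpoint decline rate over session-end readings agrees with
        a finite-difference rate taken on the true composite trajectory.
        (The OLS slope legitimately differs on a convex decaying course,
        so the oracle comparison uses the two-point estimator.)"""
        prof = NeonateProfile("n", "s", 4.0, 11.2, default_kinetics(11.2))
        course = simulate_course(prof, schedule, ZERO_NOISE)
        series = series_from_course(course, schedule)
        rate = decline_rate(series, method="endpoint")
        tbl = course.tbl_true()
        t0, t1 = schedule.session_end(1), schedule.session_end(schedule.n_cycles)
        i0 = int(np.argmin(np.abs(course.times - t0)))
        i1 = int(np.argmin(np.abs(course.times - t1)))
        fd = -(tbl[i1] - tbl[i0]) / (course.times[i1] - course.times[i0])
        assert rate == pytest.approx(fd, rel=0.05)


class TestSeriesFromMeasurements:
    def test_round_trip_from_frame(self, schedule):
        import pandas as pd

        rows = [
            ("n1", "A", 0.0, "pre", "TBL", 13.0),
            ("n1", "A", 3.0, "out", "TBL", 12.0),
            ("n1", "A", 10 / 3, "return", "TBL", 12.3),
            ("n1", "A", 3 + 10 / 3, "out", "TBL", 11.5),
            ("n1", "A", 2 * 10 / 3, "return", "TBL", 11.4),
            ("n1", "A", 0.0, "pre", "TSB", 10.5),
        ]
        df = pd.DataFrame(
            rows,
            columns=["neonate_id", "site_id", "time_h", "phase", "kind", "value_mg_dl"],
        )
        series = series_from_measurements(df)
        assert len(series) == 1
        s = series[0]
        assert s.baseline_tbl == 13.0
        assert len(s.cycles) == 2
        assert s.cycles[0].delta == pytest.approx(0.3)
        assert s.tsb_anchors == (("pre", 10.5),)

    def test_trailing_unmatched_out_dropped(self):
        import pandas as pd

        rows = [
            ("n1", "A", 0.0, "pre", "TBL", 13.0),
            ("n1", "A", 3.0, "out", "TBL", 12.0),
            ("n1", "A", 10 / 3, "return", "TBL", 12.3),
            ("n1", "A", 3 + 10 / 3, "out", "TBL", 11.5),
        ]
        df = pd.DataFrame(
            rows,
            columns=["neonate_id", "site_id", "time_h", "phase", "kind", "value_mg_dl"],
        )
        assert len(series_from_measurements(df)[0].cycles) == 1

    def test_missing_pre_reading_is_an_error(self):
        import pandas as pd

        df = pd.DataFrame(
            [("n1", "A", 3.0, "out", "TBL", 12.0)],
            columns=["neonate_id", "site_id", "time_h", "phase", "kind", "value_mg_dl"],
        )
        with pytest.raises(ValueError, match="pre-treatment"):
            series_from_measurements(df)
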