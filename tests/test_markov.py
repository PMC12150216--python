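import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rbpm_cea import markov
from rbpm_cea.errors import CalibrationError
from rbpm_cea.markov import (
    DEATH, MORB, NORM, READM, UNREC,
    TransitionMatrix, accrue, build_transition_matrix, calibrate_base_case,
    evaluate_arm, extrapolate_year, run_cohort,
)


def _random_valid_params(params, draw):
    """Overlay random (but valid) probabilities onto the default set."""
    p_mild, p_sev, p_morb, p_death = draw
    return params.with_values(
        p_mild=p_mild, p_sev=p_sev, p_morb=p_morb, p_death=p_death,
    )


class TestTransitionMatrix:
    @given(
        p_mild=st.floats(0.0, 0.2),
        p_sev=st.floats(0.0, 0.05),
        p_morb=st.floats(0.0, 0.01),
        p_death=st.floats(0.0, 0.01),
        ack=st.floats(0.0, 1.0),
    )
    def test_rows_stochastic_for_any_valid_parameters(
        self, params, p_mild, p_sev, p_morb, p_death, ack
    ):
        p = _random_valid_params(params, (p_mild, p_sev, p_morb, p_death))
        p = p.with_value("ack_sev_rbpm", ack)
        for strategy in markov.STRATEGIES:
            m = build_transition_matrix(p, strategy, "mechanistic").matrix
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(m >= -1e-12)

    def test_death_row_absorbing(self, params):
        m = build_transition_matrix(params, "rbpm", "mechanistic").matrix
        expected = np.zeros(6)
        expected[DEATH] = 1.0
        assert np.array_equal(m[DEATH], expected)

    def test_mechanistic_acknowledged_severe_flow(self, params):
        # normotensive -> readmitted = p_sev * ack_sev_rbpm = 0.008 * 0.86
        m = build_transition_matrix(params, "rbpm", "mechanistic").matrix
        assert m[NORM, READM] == pytest.approx(0.00688, abs=1e-12)
        assert m[NORM, UNREC] == pytest.approx(0.008 * 0.14, abs=1e-12)

    def test_readmitted_is_one_day_tunnel(self, params):
        m = build_transition_matrix(params, "usual_care", "mechanistic").matrix
        assert m[READM, NORM] == 1.0

    def test_direct_mode_hits_readmission_inputs(self, params):
        for strategy, target in [("rbpm", 0.01), ("usual_care", 0.05)]:
            tm = build_transition_matrix(params, strategy, "direct")
            trace = run_cohort(tm)
            assert trace.cum_readmissions[-1] == pytest.approx(target, abs=1e-9)

    def test_direct_mode_unreachable_target_raises(self, params):
        p = params.with_value("p_sev", 0.0005)  # too little severe BP for 5%
        with pytest.raises(CalibrationError, match="achievable"):
            build_transition_matrix(p, "usual_care", "direct")

    def test_invalid_matrix_rejected(self):
        bad = np.eye(6)
        bad[0, 0] = 0.5  # row no longer sums to 1
        with pytest.raises(Exception):
            TransitionMatrix(bad, "rbpm", "mechanistic")


class TestRunCohort:
    def test_identity_matrix_keeps_occupancy_constant(self):
        tm = TransitionMatrix(np.eye(6), "rbpm", "mechanistic")
        trace = run_cohort(tm)
        assert np.allclose(trace.occupancy, trace.occupancy[0])
        assert trace.cum_readmissions[-1] == 0.0

    def test_immediate_death_matrix(self):
        m = np.zeros((6, 6))
        m[:, DEATH] = 1.0
        trace = run_cohort(TransitionMatrix(m, "rbpm", "mechanistic"))
        assert np.all(trace.cum_deaths[1:] == 1.0)

    def test_occupancy_stays_on_simplex(self, params, calibration):
        for strategy in markov.STRATEGIES:
            tm = build_transition_matrix(params, strategy, "direct",
                                         calibration.ack_scale[strategy])
            trace = run_cohort(tm)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(np.diff(trace.cum_readmissions) >= -1e-15)
            assert np.all(np.diff(trace.cum_deaths) >= -1e-15)
            assert np.all(np.diff(trace.cum_morbidity) >= -1e-15)

    def test_trace_export_long_format(self, params):
        tm = build_transition_matrix(params, "rbpm", "mechanistic")
        frame = run_cohort(tm).to_frame()
        assert len(frame) == 15 * 6
        assert set(frame.columns) >= {"day", "state", "occupancy",
                                      "cum_readmissions", "cum_deaths"}


class TestAccrual:
    def test_zero_utilities_zero_qalys(self, params):
        p = params.with_values(u_norm=0.0, u_mild=0.0, u_sev=0.0, u_morb=0.0,
                               u_persistent_decrement=0.0)
        arm = evaluate_arm(p, "rbpm", mode="mechanistic")
        assert arm.qaly_total == 0.0

    def test_no_events_cost_is_fixed_cost(self, params):
        # remove every readmission/morbidity pathway: cost collapses to
        # program + cuff + nurse = 139 + 50 + 141.53
        p = params.with_values(p_sev=0.0, p_morb=0.0)
        arm = evaluate_arm(p, "rbpm", mode="mechanistic")
        assert arm.total_cost == pytest.approx(330.53, abs=1e-9)

    def test_equal_fixed_costs_and_free_readmissions_equalize_arms(self, params):
        p = params.with_values(c_readm=0.0, c_program=0.0, c_cuff=0.0,
                               c_nurse_annual=0.0, c_outpatient=0.0)
        rbpm = evaluate_arm(p, "rbpm")
        usual = evaluate_arm(p, "usual_care")
        assert rbpm.total_cost == pytest.approx(usual.total_cost, abs=1e-12)

    def test_cost_difference_monotone_in_readmission_cost(self, params):
        # usual care readmits more, so its cost grows faster with c_readm
        diffs = []
        for c in (0.0, 10_000.0, 30_000.0):
            p = params.with_value("c_readm", c)
            diffs.append(evaluate_arm(p, "usual_care").total_cost
                         - evaluate_arm(p, "rbpm").total_cost)
        assert diffs[0] <= diffs[1] <= diffs[2]


class TestExtrapolation:
    def test_no_persistence_no_uplift_equalizes_arms(self, params, calibration):
        p = params.with_value("persistent_htn_fraction", 0.0)
        tm = build_transition_matrix(p, "rbpm", "direct",
                                     calibration.ack_scale["rbpm"])
        trace = run_cohort(tm)
        q_rbpm = extrapolate_year(trace, p, "rbpm", rbpm_uplift=0.0)
        q_usual = extrapolate_year(trace, p, "usual_care", rbpm_uplift=0.0)
        assert q_rbpm == q_usual

    def test_extinct_cohort_accrues_nothing(self, params):
        m = np.zeros((6, 6))
        m[:, DEATH] = 1.0
        trace = run_cohort(TransitionMatrix(m, "rbpm", "mechanistic"))
        assert extrapolate_year(trace, params, "rbpm") == 0.0


class TestCalibration:
    def test_reproduces_published_totals(self, params, calibration, base_arms):
        rbpm, usual = base_arms
        assert rbpm.total_cost == pytest.approx(2987.92, abs=1e-6)
        assert usual.total_cost == pytest.approx(4213.99, abs=1e-6)
        assert rbpm.readmissions == pytest.approx(0.01, abs=1e-9)
        assert usual.readmissions == pytest.approx(0.05, abs=1e-9)

    def test_qaly_gain_matches_icer_implied_target(self, calibration, base_arms):
        rbpm, usual = base_arms
        gain = rbpm.qaly_total - usual.qaly_total
        assert gain == pytest.approx(calibration.qaly_gain_target, abs=1e-12)
        assert calibration.qaly_gain_target == pytest.approx(
            (4213.99 - 2987.92) / 630093.70, rel=1e-12
        )

    def test_deterministic_re_run(self, params, calibration):
        again = calibrate_base_case(params)
        assert again == calibration

    def test_constants_within_physical_bounds(self, calibration):
        for s in markov.STRATEGIES:
            assert 0.0 <= calibration.ack_scale[s]
            assert calibration.overhead[s] >= 0.0
        assert 0.0 <= calibration.rbpm_uplift <= 0.02

    def test_round_trip_serialization(self, calibration, tmp_path):
        path = tmp_path / "cal.json"
        calibration.save(path)
        loaded = markov.Calibration.load(path)
        assert loaded == dataclasses.replace(calibration)

    def test_multiplicative_variant_also_matches_totals(self, params):
        cal = calibrate_base_case(params, residual="multiplicative")
        rbpm = evaluate_arm(params, "rbpm", cal)
        usual = evaluate_arm(params, "usual_care", cal)
        assert rbpm.total_cost == pytest.approx(2987.92, abs=1e-6)
        assert usual.total_cost == pytest.approx(4213.99, abs=1e-6)
        assert all(v == 0.0 for v in cal.overhead.values())

    def test_unreachable_cost_target_raises(self, params):
        with pytest.raises(CalibrationError):
            calibrate_base_case(params, cost_targets={"rbpm": 100.0,
                                                      "usual_care": 4213.99})
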