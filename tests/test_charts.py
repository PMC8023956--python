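"""Chart engine: design construction, score recursion, program logic."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lccusum.charts import (
    AbsorbingStateError,
    ChartState,
    DesignError,
    IntegerProgramDesign,
    build_design,
    consecutive_successes_to_signal,
    run_chart,
    run_integer_program,
    run_level,
    update_chart,
)


class TestBuildDesign:
    def test_clinical_parameters_reproduce_published_increments(self, clinical_design):
        assert round(clinical_design.success_increment, 3) == 0.057
        assert round(clinical_design.failure_increment, 3) == -0.405
        assert clinical_design.unacceptable_failure_rate == pytest.approx(0.15)

    def test_loglikelihood_formula_on_other_rates(self):
        # direct evaluation of ln((1-p1)/(1-p0)) and ln(p1/p0)
        d = build_design(0.06, 0.06, signal_limit=0.5, horizon=50)
        assert d.success_increment == pytest.approx(math.log(0.94 / 0.88))
        assert d.failure_increment == pytest.approx(math.log(0.06 / 0.12))

    @pytest.mark.parametrize(
        "p1, delta, match",
        [
            (0.0, 0.05, "acceptable_failure_rate"),
            (1.0, 0.05, "acceptable_failure_rate"),
            (0.10, 0.0, "equivalence_delta"),
            (0.10, -0.01, "equivalence_delta"),
            (0.60, 0.40, "equivalence_delta|< 1"),
        ],
    )
    def test_invalid_rates_name_the_offending_field(self, p1, delta, match):
        with pytest.raises(DesignError, match=match):
            build_design(p1, delta)

    def test_unreachable_limit_within_horizon_rejected(self):
        with pytest.raises(DesignError, match="horizon"):
            build_design(0.10, 0.05, signal_limit=5.0, horizon=50)

    @given(
        p1=st.floats(0.01, 0.5),
        delta=st.floats(0.01, 0.4),
    )
    def test_increment_likelihood_identity(self, p1, delta):
        """exp(Ws)(1-p0) = 1-p1 and exp(Wf) p0 = p1 to machine precision."""
        d = build_design(p1, delta, signal_limit=1e-6, horizon=10**9)
        p0 = d.unacceptable_failure_rate
        assert math.exp(d.success_increment) * (1 - p0) == pytest.approx(
            1 - p1, abs=1e-12
        )
        assert math.exp(d.failure_increment) * p0 == pytest.approx(p1, abs=1e-12)


class TestUpdateChart:
    def test_failure_at_floor_is_clamped(self, clinical_design):
        s = update_chart(ChartState(), passed=False, design=clinical_design)
        assert s.score == 0.0
        assert not s.signalled

    def test_thirteenth_success_crosses_the_limit(self, clinical_design):
        s = ChartState()
        for _ in range(12):
            s = update_chart(s, True, clinical_design)
        assert s.score == pytest.approx(12 * clinical_design.success_increment)
        assert not s.signalled
        s = update_chart(s, True, clinical_design)
        assert s.signalled and s.signal_index == 13

    def test_mid_chart_failure_arithmetic(self, clinical_design):
        s = ChartState(score=0.5, procedures_observed=9)
        s = update_chart(s, False, clinical_design)
        assert s.score == pytest.approx(0.5 - 0.4054651, abs=1e-6)

    def test_signalled_state_is_absorbing(self, clinical_design):
        s = ChartState(score=0.75, procedures_observed=14, signalled=True, signal_index=14)
        with pytest.raises(AbsorbingStateError):
            update_chart(s, True, clinical_design)


class TestRunChart:
    def test_consecutive_passes_signal_at_thirteen(self, clinical_design):
        traj, sig = run_chart([True] * 13, clinical_design)
        assert sig == 13 and len(traj) == 13

    def test_twelve_passes_do_not_signal(self, clinical_design):
        _, sig = run_chart([True] * 12, clinical_design)
        assert sig is None

    def test_empty_sequence_is_not_an_error(self, clinical_design):
        assert run_chart([], clinical_design) == ([], None)

    def test_longer_than_horizon_truncates_with_warning(self, clinical_design):
        with pytest.warns(UserWarning, match="truncated"):
            traj, sig = run_chart([False] * 60, clinical_design)
        assert len(traj) == 50 and sig is None

    def test_updates_stop_at_signal(self, clinical_design):
        traj, sig = run_chart([True] * 20, clinical_design)
        assert sig == 13 and len(traj) == 13

    @given(st.lists(st.booleans(), min_size=0, max_size=50))
    def test_rerun_of_prefix_reproduces_trajectory(self, outcomes):
        design = build_design(0.10, 0.05, signal_limit=0.74, horizon=50)
        traj, sig = run_chart(outcomes, design)
        k = len(traj) // 2
        traj2, _ = run_chart(outcomes[:k], design)
        assert traj2 == traj[:k]

    @given(st.lists(st.booleans(), min_size=13, max_size=50), st.randoms())
    def test_permuting_outcomes_after_signal_never_changes_signal(self, outcomes, rnd):
        design = build_design(0.10, 0.05, signal_limit=0.74, horizon=50)
        _, sig = run_chart(outcomes, design)
        if sig is None:
            return
        tail = outcomes[sig:]
        rnd.shuffle(tail)
        _, sig2 = run_chart(outcomes[:sig] + tail, design)
        assert sig2 == sig

    @given(
        p1=st.floats(0.02, 0.4),
        delta=st.floats(0.02, 0.3),
        limit=st.floats(0.1, 2.0),
    )
    def test_consecutive_success_signal_count_matches_ceiling(self, p1, delta, limit):
        design = build_design(p1, delta, signal_limit=limit, horizon=10_000)
        k = consecutive_successes_to_signal(design)
        _, sig = run_chart([True] * min(k, 10_000), design)
        assert sig == k
        _, sig_short = run_chart([True] * (k - 1), design)
        assert sig_short is None


class TestIntegerProgram:
    def test_flawless_run_passes_in_exactly_39(self, integer_design):
        res = run_integer_program([[True] * 13] * 3, integer_design)
        assert res.program_passed
        assert res.total_procedures == 39
        assert res.per_level_signal_indices == (13, 13, 13)
        assert res.per_level_traces[2][-1] == 39

    def test_failure_clamps_to_level_floor_cl0(self, integer_design):
        trace, _ = run_level([True] * 5 + [False], integer_design, level=0)
        assert trace[-1] == 0  # 5 - 7 clamps at floor 0

    def test_failure_clamps_to_level_floor_cl1(self, integer_design):
        # score 14 (floor 13 + one success), then a failure: clamps to 13, not 7
        trace, _ = run_level([True, False], integer_design, level=1)
        assert trace == [14, 13]

    def test_cap_reached_without_signal_fails_program(self, integer_design):
        # longest pass run is 12 within 50 outcomes; double failures wipe
        # the accumulated score, so the chart never signals
        outcomes = ([True] * 12 + [False, False]) * 3 + [True] * 8
        assert len(outcomes) == 50
        res = run_integer_program([outcomes, [], []], integer_design)
        assert not res.per_level_signalled[0]
        assert not res.program_passed
        # later levels untouched in default mode
        assert res.per_level_procedure_counts[1:] == (0, 0)

    def test_wrong_number_of_sequences_rejected(self, integer_design):
        with pytest.raises(DesignError, match="3 outcome sequences"):
            run_integer_program([[True]], integer_design)

    def test_allow_overrun_records_late_signal_but_fails_verdict(self, integer_design):
        # signal arrives at procedure 55 (> cap 50): trace extends, level fails
        outcomes = [False] * 42 + [True] * 13
        res = run_integer_program(
            [outcomes, [True] * 13, [True] * 13], integer_design, allow_overrun=True
        )
        assert res.per_level_signal_indices[0] == 55
        assert not res.per_level_signalled[0]
        assert not res.program_passed
        # later levels still evaluated in overrun mode
        assert res.per_level_signalled[1] and res.per_level_signalled[2]

    def test_thirtyeight_procedures_cannot_pass(self, integer_design):
        # each level needs >= 13 procedures; 12 passes at a level never signal
        _, sig = run_level([True] * 12, integer_design, level=0)
        assert sig is None

    @given(st.lists(st.booleans(), min_size=0, max_size=60))
    def test_level_scores_stay_inside_their_band(self, outcomes):
        design = IntegerProgramDesign()
        for level in range(3):
            trace, sig = run_level(outcomes, design, level)
            floor = level * design.level_width
            ceiling = floor + design.level_width
            assert all(floor <= s <= ceiling for s in trace)
            if sig is not None:
                assert trace[-1] == ceiling

    def test_design_invariants_validated(self):
        with pytest.raises(DesignError):
            IntegerProgramDesign(success_step=0)
        with pytest.raises(DesignError):
            IntegerProgramDesign(failure_step=7)
        with pytest.raises(DesignError):
            IntegerProgramDesign(per_level_cap=10)  # signal needs 13
        assert IntegerProgramDesign().program_target == 39
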