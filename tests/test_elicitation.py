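"""Indifference search: utility formulas, state machine, convergence."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_indifference
from ttocapi import (
    Choice,
    DOMINANCE_VIOLATION,
    FLOOR_CENSORED,
    TerminationReason,
    ThresholdRespondent,
    TTOParams,
    apply_choice,
    begin_task,
    max_iterations,
    run_interview,
    utility_conventional,
    utility_from_state,
    utility_leadtime,
)
from ttocapi.elicitation import (
    InterviewStateError,
    RespondentError,
    describe_life_b,
)


class TestUtilityFormulas:
    @pytest.mark.parametrize(
        "a,expected",
        [(20, 1.0), (10, 0.0), (0, -1.0), (15, 0.5)],
    )
    def test_leadtime_anchors(self, a, expected, params):
        assert utility_leadtime(a, params) == pytest.approx(expected)

    def test_leadtime_domain(self, params):
        with pytest.raises(ValueError):
            utility_leadtime(20.5, params)
        with pytest.raises(ValueError):
            utility_leadtime(-0.5, params)

    @pytest.mark.parametrize("a,expected", [(10, 1.0), (0, 0.0), (7.5, 0.75)])
    def test_conventional_anchors(self, a, expected):
        assert utility_conventional(a, 10) == pytest.approx(expected)

    def test_conventional_domain(self):
        with pytest.raises(ValueError):
            utility_conventional(11, 10)


class TestStateMachine:
    def test_search_starts_at_maximum_duration(self, params):
        state = begin_task(params)
        assert state.a_current == 20.0
        assert (state.lower_bound, state.upper_bound) == (0.0, 20.0)
        assert state.history == () and not state.terminated

    def test_start_scales_with_parameters(self):
        state = begin_task(TTOParams(lead_time_l=5, disease_time_t=10))
        assert state.a_current == 15.0

    def test_equivalence_at_start_scores_full_health(self, params):
        state = apply_choice(begin_task(params), Choice.EQUIVALENT, params)
        assert state.terminated
        assert state.termination_reason is TerminationReason.EQUIVALENCE
        result = utility_from_state(state, params)
        assert result.utility == pytest.approx(1.0)
        assert result.indifference_a == 20.0

    def test_life_a_bisects_downward(self, params):
        state = apply_choice(begin_task(params), Choice.LIFE_A, params)
        assert state.upper_bound == 20.0
        assert state.a_current == 10.0  # midpoint of (0, 20) on the grid

    def test_life_b_at_maximum_flags_dominance(self, params):
        state = apply_choice(begin_task(params), Choice.LIFE_B, params)
        assert DOMINANCE_VIOLATION in state.flags
        # bracket collapses at the top: utility 1.0 but flagged
        result = utility_from_state(state, params)
        assert result.utility == pytest.approx(1.0)
        assert DOMINANCE_VIOLATION in result.flags

    def test_history_is_append_only(self, params):
        state = begin_task(params)
        presented = []
        for choice in [Choice.LIFE_A, Choice.LIFE_B, Choice.LIFE_A]:
            presented.append((state.a_current, choice))
            state = apply_choice(state, choice, params)
        assert list(state.history) == presented

    def test_choice_after_termination_is_an_error(self, params):
        state = apply_choice(begin_task(params), Choice.EQUIVALENT, params)
        with pytest.raises(InterviewStateError):
            apply_choice(state, Choice.LIFE_A, params)

    def test_utility_requires_termination(self, params):
        with pytest.raises(InterviewStateError):
            utility_from_state(begin_task(params), params)

    def test_floor_preference_is_censored(self, params):
        result = run_interview(params, lambda a: Choice.LIFE_A)
        assert result.termination_reason is TerminationReason.FLOOR
        assert result.utility == pytest.approx(-1.0)
        assert FLOOR_CENSORED in result.flags


class TestRunInterview:
    def test_always_equivalent_takes_one_iteration(self, params):
        transcript = []
        result = run_interview(
            params, lambda a: Choice.EQUIVALENT, transcript=transcript
        )
        assert result.utility == pytest.approx(1.0)
        assert len(transcript) == 1

    def test_threshold_quarter_recovered_within_tolerance(self, params):
        result = run_interview(params, ThresholdRespondent(0.25))
        assert abs(result.utility - 0.25) <= 0.05

    def test_respondent_exception_is_chained(self, params):
        def bad(a):
            raise ZeroDivisionError("boom")

        with pytest.raises(RespondentError) as excinfo:
            run_interview(params, bad)
        assert isinstance(excinfo.value.__cause__, ZeroDivisionError)

    def test_dominance_reask_consults_respondent_twice(self, params):
        calls = []
        warnings = []

        def stubborn(a):
            calls.append(a)
            return Choice.LIFE_B if len(calls) < 2 else Choice.EQUIVALENT

        result = run_interview(
            params, stubborn, dominance_policy="reask",
            on_dominance=warnings.append,
        )
        assert calls == [20.0, 20.0]  # same duration asked twice
        assert len(warnings) == 1
        assert result.utility == pytest.approx(1.0)
        assert DOMINANCE_VIOLATION not in result.flags  # corrected on re-ask

    def test_life_b_description_is_constant_across_iterations(self, params):
        descriptions = []

        def respondent(a):
            descriptions.append(describe_life_b(params, "severe AD"))
            return ThresholdRespondent(-0.3)(a)

        run_interview(params, respondent)
        assert len(set(descriptions)) == 1
        assert "10 years living with severe AD" in descriptions[0]


GRID_USTARS = [round(-1 + 0.05 * i, 10) for i in range(41)]


class TestConvergence:
    @pytest.mark.parametrize("u_star", GRID_USTARS)
    def test_bisection_matches_brute_force_oracle_on_grid(self, u_star, params):
        result = run_interview(params, ThresholdRespondent(u_star))
        assert result.indifference_a == pytest.approx(
            brute_force_indifference(u_star)
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(u_star=st.floats(min_value=-1, max_value=1))
    def test_recovery_within_one_grid_step_for_any_threshold(self, u_star):
        params = TTOParams()
        result = run_interview(params, ThresholdRespondent(u_star))
        assert abs(result.utility - u_star) <= params.grid_step / params.disease_time_t

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(u_star=st.floats(min_value=-1, max_value=1))
    def test_bracket_always_contains_true_utility(self, u_star):
        from ttocapi.elicitation import apply_choice, begin_task

        params = TTOParams()
        respondent = ThresholdRespondent(u_star)
        state = begin_task(params)
        while not state.terminated:
            lo = utility_leadtime(state.lower_bound, params)
            hi = utility_leadtime(state.upper_bound, params)
            assert lo - respondent.eps <= u_star <= hi + respondent.eps
            state = apply_choice(state, respondent(state.a_current), params)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        choices=st.lists(
            st.sampled_from([Choice.LIFE_A, Choice.LIFE_B, Choice.EQUIVALENT]),
            max_size=20,
        )
    )
    def test_any_choice_sequence_terminates_within_log_bound(self, choices):
        params = TTOParams()
        bound = max_iterations(params)
        assert bound == math.ceil(math.log2(40)) + 2
        it = iter(choices)
        transcript = []
        result = run_interview(
            params,
            lambda a: next(it, Choice.EQUIVALENT),
            dominance_policy="record",
            transcript=transcript,
        )
        assert len(transcript) <= bound
        assert result.termination_reason is not TerminationReason.NONE

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        choices=st.lists(
            st.sampled_from([Choice.LIFE_A, Choice.LIFE_B]), max_size=20
        )
    )
    def test_presented_durations_stay_on_grid_within_bounds(self, choices):
        params = TTOParams()
        state = begin_task(params)
        for choice in choices:
            if state.terminated:
                break
            assert params.on_grid(state.a_current)
            assert (
                state.lower_bound - 1e-9
                <= state.a_current
                <= state.upper_bound + 1e-9
            )
            state = apply_choice(state, choice, params)
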