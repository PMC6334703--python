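"""Lead-time TTO indifference search and utility scoring.

The search starts at the largest presentable Life A duration ``a = l + t``
(20 years for the default task) and bisects the bracket of durations
consistent with the choices so far, always presenting grid values:

* choosing **Life A** (the full-health life) means the respondent's
  indifference point lies below the presented duration — the upper bound
  moves down;
* choosing **Life B** moves the lower bound up;
* **equivalent** terminates the search at the presented duration.

Midpoints falling between grid points snap downward.  When the bracket has
shrunk to a single grid step the search stops and the indifference point is
the bracket midpoint, except that a never-presented lower bound of zero is
probed first: a respondent who still prefers Life A at 0 years (immediate
death over Life B) is censored at the formula floor ``u = -l/t`` and
flagged :data:`~ttocapi.core_model.FLOOR_CENSORED`.

Life B is identical at every iteration: ``l`` years of full health followed
by ``t`` years in the health state — only Life A varies.
"""

from __future__ import annotations

import math
from dataclasses import replace
from datetime import datetime, timezone
from typing import Callable, MutableSequence, Optional

from .core_model import (
    DOMINANCE_VIOLATION,
    FLOOR_CENSORED,
    GRID_TOL,
    Choice,
    IterationState,
    TerminationReason,
    TTOParams,
    UtilityResult,
)

__all__ = [
    "InterviewStateError",
    "RespondentError",
    "utility_leadtime",
    "utility_conventional",
    "indifference_duration",
    "begin_task",
    "apply_choice",
    "utility_from_state",
    "max_iterations",
    "run_interview",
    "describe_life_a",
    "describe_life_b",
]

Respondent = Callable[[float], Choice]


class InterviewStateError(RuntimeError):
    """A choice was applied to a terminated state, or a result was
    requested from a running one."""


class RespondentError(RuntimeError):
    """The respondent callable raised; the original exception is chained."""


def utility_leadtime(a: float, params: TTOParams = TTOParams()) -> float:
    """Health utility ``(a - l) / t`` at indifference duration ``a``.

    ``a`` is the total Life A duration in full health.  The score is 1 at
    ``a = l + t`` (full health), 0 at ``a = l`` (death) and negative below
    the lead time — states worse than death down to ``-l/t``.
    """
    if a < -GRID_TOL or a > params.life_a_max + GRID_TOL:
        raise ValueError(
            f"Life A duration {a} outside [0, {params.life_a_max}] years"
        )
    return (a - params.lead_time_l) / params.disease_time_t


def utility_conventional(a: float, t: float = 10.0) -> float:
    """Conventional (no lead time) TTO utility ``a / t``; bounded to [0, 1]."""
    if t <= 0:
        raise ValueError("t must be positive")
    if a < -GRID_TOL or a > t + GRID_TOL:
        raise ValueError(f"Life A duration {a} outside [0, {t}] years")
    return a / t


def indifference_duration(u: float, params: TTOParams = TTOParams()) -> float:
    """Life A duration whose lead-time utility is ``u`` (inverse formula)."""
    return params.lead_time_l + u * params.disease_time_t


def begin_task(params: TTOParams = TTOParams()) -> IterationState:
    """Fresh search state: first presented duration is ``l + t`` years."""
    a_max = params.life_a_max
    return IterationState(a_current=a_max, lower_bound=0.0, upper_bound=a_max)


def apply_choice(
    state: IterationState, choice: Choice, params: TTOParams = TTOParams()
) -> IterationState:
    """Advance the search by one choice; returns the new state.

    A Life B choice at the maximum duration is a dominance violation (the
    disease life rated above an equally long full-health life); it is
    recorded with the :data:`DOMINANCE_VIOLATION` flag — interactive
    front ends re-ask first (see :func:`run_interview`).
    """
    from .validation import check_dominance  # late import to avoid a cycle

    if state.terminated:
        raise InterviewStateError("cannot apply a choice to a terminated task")
    a = state.a_current
    if not params.on_grid(a):
        raise ValueError(f"presented duration {a} is off the grid")

    history = state.history + ((a, choice),)
    flags = state.flags
    if check_dominance(a, choice, params) is not None and DOMINANCE_VIOLATION not in flags:
        flags = flags + (DOMINANCE_VIOLATION,)

    if choice is Choice.EQUIVALENT:
        return replace(
            state,
            history=history,
            flags=flags,
            terminated=True,
            termination_reason=TerminationReason.EQUIVALENCE,
            indifference_a=a,
        )

    lower, upper = state.lower_bound, state.upper_bound
    if choice is Choice.LIFE_A:
        if a <= GRID_TOL:
            # Immediate death preferred to Life B: censor at the floor.
            return replace(
                state,
                history=history,
                flags=flags + (FLOOR_CENSORED,),
                terminated=True,
                termination_reason=TerminationReason.FLOOR,
                indifference_a=0.0,
            )
        upper = a
    else:
        lower = a

    if upper - lower <= params.grid_step + GRID_TOL:
        # Bracket is down to one step.  Probe a never-presented floor
        # first so the censoring branch stays reachable.
        zero_unprobed = lower <= GRID_TOL and not any(
            abs(h_a) <= GRID_TOL for h_a, _ in history
        )
        if zero_unprobed:
            return replace(
                state,
                a_current=0.0,
                lower_bound=lower,
                upper_bound=upper,
                history=history,
                flags=flags,
            )
        mid = round((lower + upper) / 2.0, 10)  # on the half-grid by construction
        return replace(
            state,
            lower_bound=lower,
            upper_bound=upper,
            history=history,
            flags=flags,
            terminated=True,
            termination_reason=TerminationReason.RESOLUTION,
            indifference_a=mid,
        )

    a_next = params.snap_down((lower + upper) / 2.0)
    assert lower + GRID_TOL < a_next < upper - GRID_TOL
    return replace(
        state,
        a_current=a_next,
        lower_bound=lower,
        upper_bound=upper,
        history=history,
        flags=flags,
    )


def utility_from_state(
    state: IterationState, params: TTOParams = TTOParams()
) -> UtilityResult:
    """Score a terminated search with the lead-time formula."""
    if not state.terminated or state.indifference_a is None:
        raise InterviewStateError("task has not terminated; no utility yet")
    return UtilityResult(
        utility=utility_leadtime(state.indifference_a, params),
        indifference_a=state.indifference_a,
        termination_reason=state.termination_reason,
        flags=state.flags,
    )


def max_iterations(params: TTOParams = TTOParams()) -> int:
    """Guaranteed iteration bound: ``ceil(log2((l+t)/step)) + 2``."""
    return math.ceil(math.log2(params.life_a_max / params.grid_step)) + 2


def run_interview(
    params: TTOParams,
    respondent: Respondent,
    *,
    dominance_policy: str = "reask",
    on_dominance: Optional[Callable[[str], None]] = None,
    transcript: Optional[MutableSequence[dict]] = None,
) -> UtilityResult:
    """Drive one TTO task to termination with a choice oracle.

    Parameters
    ----------
    respondent
        Callable mapping the presented Life A duration (years) to a
        :class:`Choice`.
    dominance_policy
        ``"reask"`` (default): on a dominance violation, warn (via
        ``on_dominance``) and ask the same duration once more before
        recording; ``"record"``: record the flagged choice silently.
    transcript
        Optional list; one dict per presented iteration is appended
        (iteration, a, choice, timestamp in ISO-8601 UTC) for CSV audit.
    """
    from .validation import DOMINANCE_MESSAGE, check_dominance

    if dominance_policy not in ("reask", "record"):
        raise ValueError(f"unknown dominance_policy {dominance_policy!r}")

    state = begin_task(params)
    limit = max_iterations(params)
    iteration = 0
    while not state.terminated:
        iteration += 1
        if iteration > limit:
            raise RuntimeError("iteration bound exceeded; schedule defect")
        a = state.a_current
        choice = _ask(respondent, a)
        if dominance_policy == "reask" and check_dominance(a, choice, params) is not None:
            if on_dominance is not None:
                on_dominance(DOMINANCE_MESSAGE)
            choice = _ask(respondent, a)
        state = apply_choice(state, choice, params)
        if transcript is not None:
            transcript.append(
                {
                    "iteration": iteration,
                    "a": a,
                    "choice": choice.name,
                    "timestamp": datetime.now(timezone.utc).isoformat(),
                }
            )
    return utility_from_state(state, params)


def _ask(respondent: Respondent, a: float) -> Choice:
    try:
        choice = respondent(a)
    except Exception as exc:
        raise RespondentError(
            f"respondent raised at Life A = {a:g} years"
        ) from exc
    if not isinstance(choice, Choice):
        raise RespondentError(
            f"respondent returned {choice!r} at Life A = {a:g} years"
        )
    return choice


def describe_life_a(a: float) -> str:
    return f"Life A: {a:g} years in full health, then death from natural causes."


def describe_life_b(params: TTOParams, health_state: str = "the health state") -> str:
    """Life B wording; independent of the iteration by construction
    (``t`` is held constant throughout the task)."""
    return (
        f"Life B: {params.lead_time_l:g} years in full health, then "
        f"{params.disease_time_t:g} years living with {health_state}, "
        "then death from natural causes."
    )
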