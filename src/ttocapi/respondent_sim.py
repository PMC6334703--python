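"""Simulated respondents and Monte-Carlo harness.

Two choice models drive the elicitation engine end to end without a human:

* :class:`ThresholdRespondent` — deterministic; holds a true utility
  ``u*`` and answers *equivalent* whenever the presented duration's
  utility is within ``eps`` of ``u*`` (default: half a grid step in
  utility units, so a ``u*`` on the measurement grid is recovered
  exactly), Life A when the presented utility exceeds ``u*``, Life B
  otherwise.
* :class:`LogisticRespondent` — stochastic; chooses Life A with
  probability ``expit((u(a) - u*)/s)`` and never answers *equivalent*, so
  every task ends by bracket resolution.  ``s`` is the noise scale in
  utility units; as ``s -> 0`` it degenerates to the threshold model.

:func:`recovery_experiment` measures how well the interview recovers known
utilities; :func:`simulate_cohort` produces complete survey records —
randomization draw, demographics, EQ-5D-5L answers and all three
health-state utilities — for pipeline tests and example data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_model import (
    Choice,
    FieldType,
    InstrumentDef,
    ProjectDef,
    SessionRecord,
    TTOParams,
    ValidationFormat,
    default_project,
)
from .elicitation import run_interview, utility_leadtime
from .survey_queue import draw_mod6, next_instrument

__all__ = [
    "ThresholdRespondent",
    "LogisticRespondent",
    "recovery_experiment",
    "simulate_cohort",
    "DEFAULT_STATE_UTILITY_MEANS",
]

#: Mean true utilities used by the default cohort factory, by instrument
#: name: plausible mild / moderate / severe dementia values (sd 0.15,
#: clipped to [-1, 1]).
DEFAULT_STATE_UTILITY_MEANS = {
    "mild_ad": 0.75,
    "moderate_ad": 0.55,
    "severe_ad": 0.30,
}
_DEFAULT_STATE_SD = 0.15

RespondentFactory = Callable[[InstrumentDef, np.random.Generator], Callable[[float], Choice]]


@dataclass
class ThresholdRespondent:
    """Deterministic respondent with a fixed indifference threshold."""

    u_star: float
    params: TTOParams = field(default_factory=TTOParams)
    eps: Optional[float] = None

    def __post_init__(self) -> None:
        if self.eps is None:
            # Half a grid step in utility units: ties equivalence to the
            # measurement grid so on-grid thresholds are hit exactly.
            self.eps = self.params.grid_step / (2.0 * self.params.disease_time_t)

    def __call__(self, a: float) -> Choice:
        u = utility_leadtime(a, self.params)
        if abs(u - self.u_star) <= self.eps:
            return Choice.EQUIVALENT
        return Choice.LIFE_A if u > self.u_star else Choice.LIFE_B


@dataclass
class LogisticRespondent:
    """Stochastic respondent with logistic choice noise (never equivalent)."""

    u_star: float
    noise_scale: float
    rng: np.random.Generator
    params: TTOParams = field(default_factory=TTOParams)

    def __post_init__(self) -> None:
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")

    def __call__(self, a: float) -> Choice:
        u = utility_leadtime(a, self.params)
        p_life_a = expit((u - self.u_star) / self.noise_scale)
        return Choice.LIFE_A if self.rng.random() < p_life_a else Choice.LIFE_B


def recovery_experiment(
    u_grid: Sequence[float],
    respondent_kind: str = "threshold",
    reps: int = 1,
    seed: int = 0,
    params: TTOParams = TTOParams(),
    noise_scale: float = 0.05,
) -> pd.DataFrame:
    """Run interviews against known true utilities and summarize recovery.

    Returns one row per ``u_star`` with columns ``u_star``,
    ``mean_recovered``, ``bias`` (mean recovered minus true) and ``mae``
    (mean absolute error), over ``reps`` replicate interviews.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if respondent_kind not in ("threshold", "logistic"):
        raise ValueError(f"unknown respondent_kind {respondent_kind!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for u_star in u_grid:
        recovered = np.empty(reps)
        for rep in range(reps):
            if respondent_kind == "threshold":
                respondent = ThresholdRespondent(u_star, params=params)
            else:
                respondent = LogisticRespondent(u_star, noise_scale, rng, params=params)
            result = run_interview(params, respondent, dominance_policy="record")
            recovered[rep] = result.utility
        rows.append(
            {
                "u_star": float(u_star),
                "mean_recovered": float(recovered.mean()),
                "bias": float(recovered.mean() - u_star),
                "mae": float(np.abs(recovered - u_star).mean()),
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)


def _default_factory(instrument: InstrumentDef, rng: np.random.Generator):
    mean = DEFAULT_STATE_UTILITY_MEANS.get(instrument.name, 0.5)
    u_star = float(np.clip(rng.normal(mean, _DEFAULT_STATE_SD), -1.0, 1.0))
    params = instrument.tto_task.params if instrument.tto_task else TTOParams()
    return ThresholdRespondent(u_star, params=params)


def _fill_fields(
    instrument: InstrumentDef,
    record: SessionRecord,
    rng: np.random.Generator,
    skip: frozenset[str] = frozenset(),
) -> None:
    """Random but valid answers for every data-storing field."""
    for f in instrument.fields:
        if not f.stores_data or f.field_type is FieldType.CALC or f.name in skip:
            continue
        choices = f.effective_choices
        if choices is not None:
            codes = list(choices)
            record.field_values[f.name] = codes[int(rng.integers(len(codes)))]
        elif f.validation_format is ValidationFormat.INTEGER:
            lo = int(f.validation_min) if f.validation_min is not None else 0
            hi = int(f.validation_max) if f.validation_max is not None else 100
            record.field_values[f.name] = int(rng.integers(lo, hi + 1))
        elif f.validation_format is ValidationFormat.EMAIL:
            record.field_values[f.name] = f"respondent{record.record_id}@example.org"


def simulate_cohort(
    n: int,
    project: Optional[ProjectDef] = None,
    respondent_factory: Optional[RespondentFactory] = None,
    seed: int = 0,
) -> list[SessionRecord]:
    """Simulate ``n`` complete survey sessions.

    Each record completes the preliminary instrument (drawing ``mod6``),
    then follows auto-start navigation through the three health-state
    tasks in the order the queue dictates, running a full TTO interview
    per task.  Bitwise reproducible for a given seed.
    """
    if project is None:
        project = default_project()
    if respondent_factory is None:
        respondent_factory = _default_factory
    rng = np.random.default_rng(seed)
    records: list[SessionRecord] = []
    for i in range(1, n + 1):
        record = SessionRecord(record_id=str(i))
        prelim = project.preliminary
        _fill_fields(prelim, record, rng, skip=frozenset({project.randomization_var}))
        record.mod6 = draw_mod6(rng)
        record.field_values[project.randomization_var] = record.mod6
        record.completion_flags[prelim.name] = 2
        while (name := next_instrument(project, record)) is not None:
            instrument = project.instrument(name)
            tto_skip = set()
            if instrument.tto_task is not None:
                params = instrument.tto_task.params
                respondent = respondent_factory(instrument, rng)
                result = run_interview(params, respondent, dominance_policy="record")
                record.utilities[name] = result
                for f in instrument.fields:
                    if f.name.endswith("_tto_indifference"):
                        record.field_values[f.name] = result.indifference_a
                        tto_skip.add(f.name)
                    elif f.name.endswith("_tto_utility"):
                        # calc field materialized by the engine
                        record.field_values[f.name] = round(result.utility, 6)
                        tto_skip.add(f.name)
            _fill_fields(instrument, record, rng, skip=frozenset(tto_skip))
            record.completion_flags[name] = 2
        records.append(record)
    return records
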