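"""Domain model for a lead-time time trade-off (TTO) interview project.

A TTO interview asks a respondent to choose repeatedly between two
hypothetical lives:

* **Life A** — ``a`` years in full health, then death;
* **Life B** — ``l`` years in full health, then ``t`` years in the health
  state being valued, then death.

``l`` is the *lead time* prepended to both lives so that states judged worse
than death remain on the scale, and ``t`` is the fixed *disease time*.  The
interview varies ``a`` until the respondent is indifferent; the health
utility of the state is then ``u = (a - l) / t``.

This module holds the value types shared by the rest of the package — the
TTO task parameters, the iteration state of the indifference search, survey
structure (fields, instruments, project) and per-respondent session records
— plus :func:`default_project`, the four-instrument Alzheimer's-disease
(AD) valuation project that the engine ships with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Mapping, Optional

__all__ = [
    "GRID_TOL",
    "DOMINANCE_VIOLATION",
    "FLOOR_CENSORED",
    "Choice",
    "TerminationReason",
    "TTOParams",
    "TTOTask",
    "IterationState",
    "UtilityResult",
    "FieldType",
    "ValidationFormat",
    "FieldDef",
    "InstrumentDef",
    "ProjectDef",
    "SessionRecord",
    "default_project",
    "project_to_dict",
    "project_from_dict",
]

#: Absolute tolerance used when comparing durations that live on the grid.
GRID_TOL = 1e-9

#: Warning flag: the respondent preferred the disease life over an
#: equally long full-health life (logically inconsistent choice).
DOMINANCE_VIOLATION = "DOMINANCE_VIOLATION"

#: Warning flag: the respondent still preferred immediate death (Life A at
#: 0 years) over Life B; the utility is censored at the formula floor -l/t.
FLOOR_CENSORED = "FLOOR_CENSORED"


class Choice(Enum):
    """The three admissible answers to one TTO iteration."""

    LIFE_A = "life_a"
    LIFE_B = "life_b"
    EQUIVALENT = "equivalent"


class TerminationReason(Enum):
    """Why the indifference search stopped (``NONE`` while still running)."""

    NONE = "none"
    #: The respondent said Life A and Life B are equivalent.
    EQUIVALENCE = "equivalence"
    #: The bracket shrank to one grid step; indifference is its midpoint.
    RESOLUTION = "resolution"
    #: Life A was preferred even at 0 years; utility censored at -l/t.
    FLOOR = "floor"


@dataclass(frozen=True)
class TTOParams:
    """Parameters of one lead-time TTO task.

    Parameters
    ----------
    lead_time_l : float
        Lead time ``l`` in years prepended to both lives (non-negative).
    disease_time_t : float
        Disease time ``t`` in years spent in the health state in Life B
        (positive, held constant across iterations).
    grid_step : float
        Resolution of the Life A duration grid in years; must divide
        ``l + t`` evenly.

    The default instance (``l=10, t=10, grid_step=0.5``) presents Life A
    durations on ``{0, 0.5, …, 20}`` years and measures utilities on a
    0.05 grid spanning ``[-1, 1]``.
    """

    lead_time_l: float = 10.0
    disease_time_t: float = 10.0
    grid_step: float = 0.5

    def __post_init__(self) -> None:
        if self.lead_time_l < 0:
            raise ValueError("lead_time_l must be non-negative")
        if self.disease_time_t <= 0:
            raise ValueError("disease_time_t must be positive")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        ratio = self.life_a_max / self.grid_step
        if abs(ratio - round(ratio)) > 1e-6:
            raise ValueError("grid_step must divide lead_time_l + disease_time_t")

    @property
    def life_a_max(self) -> float:
        """Largest presentable Life A duration, ``l + t`` years."""
        return self.lead_time_l + self.disease_time_t

    @property
    def n_grid(self) -> int:
        return int(round(self.life_a_max / self.grid_step))

    def grid(self) -> tuple[float, ...]:
        """All presentable Life A durations, ``0, step, …, l + t``."""
        return tuple(round(i * self.grid_step, 10) for i in range(self.n_grid + 1))

    def on_grid(self, a: float) -> bool:
        if a < -GRID_TOL or a > self.life_a_max + GRID_TOL:
            return False
        ratio = a / self.grid_step
        return abs(ratio - round(ratio)) <= 1e-6

    def snap_down(self, x: float) -> float:
        """Largest grid point <= ``x`` (deterministic midpoint tie-break)."""
        return round(math.floor(x / self.grid_step + GRID_TOL) * self.grid_step, 10)


@dataclass(frozen=True)
class TTOTask:
    """A TTO task attached to an instrument: parameters plus the label of
    the health state being valued."""

    health_state: str
    params: TTOParams = TTOParams()


@dataclass(frozen=True)
class IterationState:
    """State of the indifference search after zero or more choices.

    Invariants: ``0 <= lower_bound <= a_current <= upper_bound <= l + t``;
    every presented duration lies on the grid; ``history`` is append-only
    and the state only changes through :func:`ttocapi.elicitation.apply_choice`.
    """

    a_current: float
    lower_bound: float
    upper_bound: float
    history: tuple[tuple[float, Choice], ...] = ()
    terminated: bool = False
    termination_reason: TerminationReason = TerminationReason.NONE
    indifference_a: Optional[float] = None
    flags: tuple[str, ...] = ()

    def probed(self, a: float) -> bool:
        return any(abs(h_a - a) <= GRID_TOL for h_a, _ in self.history)


@dataclass(frozen=True)
class UtilityResult:
    """Outcome of one completed TTO task.

    ``utility`` lies in ``[-l/t, 1]`` (``[-1, 1]`` for the default task);
    ``indifference_a`` is the Life A duration (years) at indifference;
    ``flags`` carries warnings such as :data:`DOMINANCE_VIOLATION` or
    :data:`FLOOR_CENSORED`.
    """

    utility: float
    indifference_a: float
    termination_reason: TerminationReason
    flags: tuple[str, ...] = ()


class FieldType(Enum):
    TEXT = "text"
    RADIO = "radio"
    DROPDOWN = "dropdown"
    YESNO = "yesno"
    DESCRIPTIVE = "descriptive"
    CALC = "calc"


class ValidationFormat(Enum):
    INTEGER = "integer"
    NUMBER = "number"
    EMAIL = "email"
    DATE = "date"


_YESNO_CHOICES: Mapping[str, str] = {"1": "Yes", "0": "No"}


@dataclass(frozen=True)
class FieldDef:
    """One survey field (a single data entry).

    RADIO/DROPDOWN fields require a non-empty ``choices`` mapping of code
    to label; CALC fields require ``calc_expression``; DESCRIPTIVE fields
    display text and store no data.
    """

    name: str
    field_type: FieldType
    label: str
    choices: Optional[Mapping[str, str]] = None
    validation_format: Optional[ValidationFormat] = None
    validation_min: Optional[float] = None
    validation_max: Optional[float] = None
    calc_expression: Optional[str] = None
    section_header: str = ""
    note: str = ""
    required: bool = False

    def __post_init__(self) -> None:
        if self.field_type in (FieldType.RADIO, FieldType.DROPDOWN) and not self.choices:
            raise ValueError(f"{self.field_type.value} field {self.name!r} requires choices")
        if self.field_type is FieldType.CALC and not self.calc_expression:
            raise ValueError(f"calc field {self.name!r} requires an expression")

    @property
    def stores_data(self) -> bool:
        return self.field_type is not FieldType.DESCRIPTIVE

    @property
    def effective_choices(self) -> Optional[Mapping[str, str]]:
        """Choice codes including the implicit Yes/No coding of YESNO fields."""
        if self.field_type is FieldType.YESNO:
            return _YESNO_CHOICES
        return self.choices


@dataclass(frozen=True)
class InstrumentDef:
    """A named group of fields completed as a unit.

    ``completion_flag_var`` is the variable holding the completion status,
    coded 2 (complete) / 0 (incomplete) so the arithmetic survey-queue
    conditions (e.g. ``[part2_complete]+[part3_complete]="4"``) work.
    An optional :class:`TTOTask` marks the instrument as a valuation task.
    """

    name: str
    fields: tuple[FieldDef, ...]
    completion_flag_var: str
    label: str = ""
    tto_task: Optional[TTOTask] = None

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(self, "label", self.name.replace("_", " ").title())
        names = [f.name for f in self.fields]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate field names in instrument {self.name!r}")


@dataclass(frozen=True)
class ProjectDef:
    """A whole survey project.

    The first instrument is the preliminary one (demographics plus the
    randomization draw); the remaining instruments are gated by the
    survey-queue ``queue_conditions`` (instrument name -> condition text in
    the queue grammar).  ``randomization_var`` names the 1..6 draw that
    selects the task order.
    """

    name: str
    instruments: tuple[InstrumentDef, ...]
    randomization_var: str = "mod6"
    queue_conditions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.instruments:
            raise ValueError("a project needs at least one instrument")
        flag_vars = [i.completion_flag_var for i in self.instruments]
        if len(set(flag_vars)) != len(flag_vars):
            raise ValueError("completion_flag_var must be unique per instrument")
        names = [i.name for i in self.instruments]
        if len(set(names)) != len(names):
            raise ValueError("instrument names must be unique")

    @property
    def preliminary(self) -> InstrumentDef:
        return self.instruments[0]

    @property
    def queued_instruments(self) -> tuple[InstrumentDef, ...]:
        """Instruments gated by the survey queue (all but the preliminary)."""
        return self.instruments[1:]

    def instrument(self, name: str) -> InstrumentDef:
        for inst in self.instruments:
            if inst.name == name:
                return inst
        raise KeyError(name)

    def declared_variables(self) -> set[str]:
        vars_: set[str] = {self.randomization_var}
        for inst in self.instruments:
            vars_.add(inst.completion_flag_var)
            vars_.update(f.name for f in inst.fields if f.stores_data)
        return vars_

    def validate(self) -> None:
        """Parse every queue condition and check it references only
        declared variables.  Raises on the first problem found."""
        from . import survey_queue  # late import to avoid a cycle

        declared = self.declared_variables()
        for name, text in self.queue_conditions.items():
            self.instrument(name)  # KeyError on unknown instrument
            expr = survey_queue.parse_condition(text)
            unknown = expr.variables() - declared
            if unknown:
                raise ValueError(
                    f"queue condition for {name!r} references undeclared "
                    f"variables: {sorted(unknown)}"
                )


@dataclass
class SessionRecord:
    """One respondent's record: the randomization draw, raw field values,
    completion flags (instrument name -> 0/2) and per-task utilities."""

    record_id: str
    mod6: Optional[int] = None
    field_values: dict[str, Any] = field(default_factory=dict)
    completion_flags: dict[str, int] = field(default_factory=dict)
    utilities: dict[str, UtilityResult] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Default Alzheimer's-disease valuation project
# --------------------------------------------------------------------------

_EQ5D_DIMENSIONS = (
    ("mobility", "Mobility"),
    ("self_care", "Self-care"),
    ("usual_activities", "Usual activities"),
    ("pain_discomfort", "Pain / discomfort"),
    ("anxiety_depression", "Anxiety / depression"),
)

_EQ5D_LEVELS: Mapping[str, str] = {
    "1": "No problems",
    "2": "Slight problems",
    "3": "Moderate problems",
    "4": "Severe problems",
    "5": "Extreme problems / unable",
}

_EDUCATION_CHOICES: Mapping[str, str] = {
    "1": "Less than high school",
    "2": "High school diploma",
    "3": "College or trade certificate",
    "4": "University degree",
    "5": "Postgraduate degree",
}

_INCOME_CHOICES: Mapping[str, str] = {
    "1": "Under $25,000",
    "2": "$25,000 to $49,999",
    "3": "$50,000 to $74,999",
    "4": "$75,000 to $99,999",
    "5": "$100,000 or more",
    "6": "Prefer not to answer",
}

_GENDER_CHOICES: Mapping[str, str] = {
    "1": "Female",
    "2": "Male",
    "3": "Other / prefer not to say",
}

# Survey-queue conditions exactly as configured in the shipped AD project
# (curly quotes included; the parser normalizes them).  Flag coding:
# part1/2/3_complete are the Mild/Moderate/Severe task flags, 2 = complete.
_AD_QUEUE_CONDITIONS: Mapping[str, str] = {
    "mild_ad": (
        "([mod6]<“3”) or ([mod6]=“3” and "
        "([part2_complete]+[part3_complete]=“2”)) or "
        "(([mod6]=“4” or [mod6]=“6”) and "
        "([part2_complete]+[part3_complete]=“4”)) or "
        "([mod6]=“5” and ([part2_complete]+[part3_complete]=“2”))"
    ),
    "moderate_ad": (
        "([mod6]=“3”) or ([mod6]=“4”) or "
        "([mod6]=“1” and ([part1_complete]+[part3_complete]=“2”)) or "
        "(([mod6]=“2” or [mod6]=“5”) and "
        "([part3_complete]+[part1_complete]=“4”)) or "
        "([mod6]=“6” and ([part1_complete]+[part3_complete]=“2”))"
    ),
    "severe_ad": (
        "([mod6]=“5”) or ([mod6]=“6”) or "
        "([mod6]=“2” and ([part1_complete]+[part2_complete]=“2”)) or "
        "(([mod6]=“1” or [mod6]=“3”) and "
        "([part2_complete]+[part1_complete]=“4”)) or "
        "([mod6]=“4” and ([part1_complete]+[part2_complete]=“2”))"
    ),
}


def _eq5d_fields(prefix: str, context: str) -> list[FieldDef]:
    return [
        FieldDef(
            name=f"{prefix}_eq5d_{dim}",
            field_type=FieldType.RADIO,
            label=f"{label} (EQ-5D-5L{context})",
            choices=_EQ5D_LEVELS,
        )
        for dim, label in _EQ5D_DIMENSIONS
    ]


def _ad_instrument(name: str, label: str, index: int, description_no: int) -> InstrumentDef:
    params = TTOParams()
    prefix = name
    fields: list[FieldDef] = [
        FieldDef(
            name=f"{prefix}_vignette",
            field_type=FieldType.DESCRIPTIVE,
            label=f"Description {description_no}",
            note=(
                f"Placeholder vignette for the {label} health state; replace "
                "with the study's own bullet-point description."
            ),
        ),
        FieldDef(
            name=f"{prefix}_tto_indifference",
            field_type=FieldType.TEXT,
            label=f"Life A duration at indifference ({label})",
            validation_format=ValidationFormat.NUMBER,
            validation_min=0.0,
            validation_max=params.life_a_max,
            note="Years of full health in Life A at the point of indifference.",
        ),
        FieldDef(
            name=f"{prefix}_tto_utility",
            field_type=FieldType.CALC,
            label=f"Health utility ({label})",
            calc_expression=(
                f"([{prefix}_tto_indifference] - {params.lead_time_l:g})"
                f"/{params.disease_time_t:g}"
            ),
        ),
    ]
    fields += _eq5d_fields(prefix, " as if living in this health state")
    return InstrumentDef(
        name=name,
        label=label,
        fields=tuple(fields),
        completion_flag_var=f"part{index}_complete",
        tto_task=TTOTask(health_state=label, params=params),
    )


def default_project() -> ProjectDef:
    """The shipped Alzheimer's-disease valuation project.

    Four instruments: Preliminary information (demographics, a question
    about knowing someone with AD, and the five EQ-5D-5L items), then one
    TTO task per AD severity (Mild, Moderate, Severe), each with its own
    EQ-5D-5L items answered as if living in that health state.  The task
    order is randomized uniformly over the six permutations by the
    ``mod6`` draw and the survey-queue conditions.
    """
    preliminary = InstrumentDef(
        name="preliminary",
        label="Preliminary information",
        completion_flag_var="preliminary_complete",
        fields=tuple(
            [
                FieldDef(
                    name="age",
                    field_type=FieldType.TEXT,
                    label="Age (years)",
                    validation_format=ValidationFormat.INTEGER,
                    validation_min=18,
                    validation_max=110,
                    required=True,
                ),
                FieldDef(
                    name="gender",
                    field_type=FieldType.RADIO,
                    label="Gender",
                    choices=_GENDER_CHOICES,
                ),
                FieldDef(
                    name="education",
                    field_type=FieldType.DROPDOWN,
                    label="Highest level of education",
                    choices=_EDUCATION_CHOICES,
                ),
                FieldDef(
                    name="income",
                    field_type=FieldType.DROPDOWN,
                    label="Annual household income",
                    choices=_INCOME_CHOICES,
                ),
                FieldDef(
                    name="email",
                    field_type=FieldType.TEXT,
                    label="Contact email (optional)",
                    validation_format=ValidationFormat.EMAIL,
                ),
                FieldDef(
                    name="knows_ad",
                    field_type=FieldType.YESNO,
                    label="Do you know someone with Alzheimer's disease?",
                ),
                FieldDef(
                    name="mod6",
                    field_type=FieldType.TEXT,
                    label="Randomization draw (assigned automatically)",
                    validation_format=ValidationFormat.INTEGER,
                    validation_min=1,
                    validation_max=6,
                    note="Uniform draw on 1-6 selecting one of the six task orders.",
                ),
            ]
            + _eq5d_fields("prelim", "")
        ),
    )
    instruments = (
        preliminary,
        _ad_instrument("mild_ad", "Mild AD", 1, 1),
        _ad_instrument("moderate_ad", "Moderate AD", 2, 2),
        _ad_instrument("severe_ad", "Severe AD", 3, 3),
    )
    return ProjectDef(
        name="ad_tto",
        instruments=instruments,
        randomization_var="mod6",
        queue_conditions=dict(_AD_QUEUE_CONDITIONS),
    )


# --------------------------------------------------------------------------
# Plain-dict (de)serialization used by the JSON/YAML config files
# --------------------------------------------------------------------------

def _field_to_dict(f: FieldDef) -> dict[str, Any]:
    d: dict[str, Any] = {
        "name": f.name,
        "type": f.field_type.value,
        "label": f.label,
    }
    if f.choices:
        d["choices"] = dict(f.choices)
    if f.validation_format is not None:
        v: dict[str, Any] = {"format": f.validation_format.value}
        if f.validation_min is not None:
            v["min"] = f.validation_min
        if f.validation_max is not None:
            v["max"] = f.validation_max
        d["validation"] = v
    if f.calc_expression:
        d["calc"] = f.calc_expression
    if f.section_header:
        d["section_header"] = f.section_header
    if f.note:
        d["note"] = f.note
    if f.required:
        d["required"] = True
    return d


def _field_from_dict(d: Mapping[str, Any]) -> FieldDef:
    v = d.get("validation", {})
    return FieldDef(
        name=d["name"],
        field_type=FieldType(d["type"]),
        label=d.get("label", d["name"]),
        choices=dict(d["choices"]) if d.get("choices") else None,
        validation_format=ValidationFormat(v["format"]) if v else None,
        validation_min=v.get("min") if v else None,
        validation_max=v.get("max") if v else None,
        calc_expression=d.get("calc"),
        section_header=d.get("section_header", ""),
        note=d.get("note", ""),
        required=bool(d.get("required", False)),
    )


def project_to_dict(project: ProjectDef) -> dict[str, Any]:
    """Plain-dict form of a project, suitable for JSON or YAML."""
    out: dict[str, Any] = {
        "name": project.name,
        "randomization_var": project.randomization_var,
        "queue_conditions": dict(project.queue_conditions),
        "instruments": [],
    }
    for inst in project.instruments:
        d: dict[str, Any] = {
            "name": inst.name,
            "label": inst.label,
            "completion_flag": inst.completion_flag_var,
            "fields": [_field_to_dict(f) for f in inst.fields],
        }
        if inst.tto_task is not None:
            p = inst.tto_task.params
            d["tto"] = {
                "health_state": inst.tto_task.health_state,
                "lead_time_l": p.lead_time_l,
                "disease_time_t": p.disease_time_t,
                "grid_step": p.grid_step,
            }
        out["instruments"].append(d)
    return out


def project_from_dict(data: Mapping[str, Any]) -> ProjectDef:
    """Inverse of :func:`project_to_dict` (round-trip safe)."""
    instruments = []
    for d in data["instruments"]:
        tto = None
        if "tto" in d:
            t = d["tto"]
            tto = TTOTask(
                health_state=t.get("health_state", d.get("label", d["name"])),
                params=TTOParams(
                    lead_time_l=float(t.get("lead_time_l", 10.0)),
                    disease_time_t=float(t.get("disease_time_t", 10.0)),
                    grid_step=float(t.get("grid_step", 0.5)),
                ),
            )
        instruments.append(
            InstrumentDef(
                name=d["name"],
                label=d.get("label", ""),
                completion_flag_var=d["completion_flag"],
                fields=tuple(_field_from_dict(f) for f in d["fields"]),
                tto_task=tto,
            )
        )
    return ProjectDef(
        name=data.get("name", "tto_project"),
        instruments=tuple(instruments),
        randomization_var=data.get("randomization_var", "mod6"),
        queue_conditions=dict(data.get("queue_conditions", {})),
    )
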