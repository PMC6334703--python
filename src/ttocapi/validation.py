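"""Field-level validation and TTO logical-error (dominance) checks.

In the interactive app these surface as pop-up alerts; in this engine they
are plain values — :func:`validate_value` returns either an :class:`Ok`
wrapping the parsed value or an :class:`Invalid` carrying a stable error
kind (``FORMAT`` or ``RANGE``) and a user-facing message, and never raises.
Front ends render the messages; the strings below are stable so they can
be localized by key.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date
from typing import Optional, Union

from .core_model import (
    GRID_TOL,
    Choice,
    FieldDef,
    FieldType,
    TTOParams,
    ValidationFormat,
)

__all__ = [
    "Ok",
    "Invalid",
    "DominanceViolation",
    "validate_value",
    "check_dominance",
    "completion_flag",
    "FORMAT",
    "RANGE",
    "DOMINANCE_MESSAGE",
]

FORMAT = "FORMAT"
RANGE = "RANGE"

#: Pop-up text shown when a choice implies the health state beats full health.
DOMINANCE_MESSAGE = (
    "Please check your answer: choosing Life B here means that living with "
    "the health state is better than spending the same years in full "
    "health. If that is really your preference, choose Life B again."
)

MESSAGES = {
    "integer": "Please enter a whole number.",
    "number": "Please enter a number.",
    "email": "Please enter a valid email address (name@example.org).",
    "date": "Please enter a date as YYYY-MM-DD.",
    "choice": "Please pick one of the listed options.",
    "range": "Value must be between {lo:g} and {hi:g}.",
}


@dataclass(frozen=True)
class Ok:
    value: object


@dataclass(frozen=True)
class Invalid:
    kind: str
    message: str


@dataclass(frozen=True)
class DominanceViolation:
    a: float
    message: str = DOMINANCE_MESSAGE


_EMAIL_RE = re.compile(r"^[^@\s]+@[^@\s]+$")


def validate_value(field: FieldDef, raw: str) -> Union[Ok, Invalid]:
    """Validate one raw entry against a field definition.

    Returns ``Ok(parsed)`` — an ``int``/``float``/``date``/``str`` as the
    format dictates — or an ``Invalid`` with kind ``FORMAT`` or ``RANGE``.
    Choice fields (radio/dropdown/yes-no) accept only their listed codes.
    """
    raw = str(raw).strip()
    choices = field.effective_choices
    if choices is not None:
        if raw in choices:
            return Ok(raw)
        return Invalid(FORMAT, MESSAGES["choice"])

    fmt = field.validation_format
    value: object = raw
    if fmt is ValidationFormat.INTEGER:
        try:
            value = int(raw)
        except ValueError:
            return Invalid(FORMAT, MESSAGES["integer"])
    elif fmt is ValidationFormat.NUMBER:
        try:
            value = float(raw)
        except ValueError:
            return Invalid(FORMAT, MESSAGES["number"])
    elif fmt is ValidationFormat.EMAIL:
        if not _EMAIL_RE.match(raw):
            return Invalid(FORMAT, MESSAGES["email"])
    elif fmt is ValidationFormat.DATE:
        try:
            value = date.fromisoformat(raw)
        except ValueError:
            return Invalid(FORMAT, MESSAGES["date"])

    if isinstance(value, (int, float)) and not isinstance(value, bool):
        lo, hi = field.validation_min, field.validation_max
        if (lo is not None and value < lo) or (hi is not None and value > hi):
            return Invalid(
                RANGE,
                MESSAGES["range"].format(
                    lo=lo if lo is not None else float("-inf"),
                    hi=hi if hi is not None else float("inf"),
                ),
            )
    return Ok(value)


def check_dominance(
    a: float, choice: Choice, params: TTOParams = TTOParams()
) -> Optional[DominanceViolation]:
    """Logical-error check for one TTO choice.

    Fires on exactly one pair per task: Life B chosen when Life A offers
    the full ``l + t`` years in full health, which implies the disease
    state is strictly better than full health.  Returns ``None`` otherwise.
    """
    if choice is Choice.LIFE_B and abs(a - params.life_a_max) <= GRID_TOL:
        return DominanceViolation(a=a)
    return None


def completion_flag(complete: bool) -> int:
    """Instrument completion code: 2 when complete, 0 when incomplete."""
    return 2 if complete else 0
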