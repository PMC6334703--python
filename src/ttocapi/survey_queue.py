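"""Survey-queue logic: uniform task-order randomization and the boolean
condition grammar gating each instrument.

The grammar is the operator subset used by REDCap-style survey queues:
variable references in square brackets, numeric literals (optionally
quoted, curly or straight quotes), comparisons ``=`` and ``<``, arithmetic
``+``, the connectives ``and`` / ``or``, and parentheses.  Quoted numerals
compare numerically, so ``[mod6]<"3"`` is true when the integer draw is 1
or 2, and ``[part2_complete]+[part3_complete]="4"`` is true exactly when
both flags carry the complete code 2.  Missing variables evaluate as 0
(incomplete), which makes every condition total before any task is done.

A single uniform draw ``mod6`` in 1..6 plus one condition per instrument
yields all six orders of the three health-state tasks, with exactly one
eligible instrument at every step ("auto start" navigation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Mapping, Optional, Union

import numpy as np

from .core_model import ProjectDef, SessionRecord

__all__ = [
    "ConditionSyntaxError",
    "QueueError",
    "AmbiguousQueueError",
    "QueueDeadlockError",
    "ConditionExpr",
    "parse_condition",
    "draw_mod6",
    "eligible_instruments",
    "next_instrument",
    "order_for",
    "queue_orders",
    "uniqueness_table",
]

_NUM_TOL = 1e-9


class ConditionSyntaxError(ValueError):
    """Malformed condition text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class QueueError(RuntimeError):
    pass


class AmbiguousQueueError(QueueError):
    """More than one instrument is eligible — the conditions are wrong."""


class QueueDeadlockError(QueueError):
    """No instrument is eligible although some remain incomplete."""


# -- expression tree -------------------------------------------------------

@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class Lit:
    value: float


@dataclass(frozen=True)
class BinOp:
    op: str  # '+', '=', '<', 'and', 'or'
    left: "Node"
    right: "Node"


Node = Union[Var, Lit, BinOp]


def _evaluate(node: Node, env: Mapping[str, float]) -> float:
    if isinstance(node, Var):
        return float(env.get(node.name, 0))
    if isinstance(node, Lit):
        return node.value
    left = _evaluate(node.left, env)
    right = _evaluate(node.right, env)
    if node.op == "+":
        return left + right
    if node.op == "=":
        return 1.0 if abs(left - right) <= _NUM_TOL else 0.0
    if node.op == "<":
        return 1.0 if left < right - _NUM_TOL else 0.0
    if node.op == "and":
        return 1.0 if (left != 0 and right != 0) else 0.0
    if node.op == "or":
        return 1.0 if (left != 0 or right != 0) else 0.0
    raise AssertionError(f"unknown operator {node.op!r}")


def _variables(node: Node) -> set[str]:
    if isinstance(node, Var):
        return {node.name}
    if isinstance(node, Lit):
        return set()
    return _variables(node.left) | _variables(node.right)


@dataclass(frozen=True)
class ConditionExpr:
    """A parsed survey-queue condition.

    Evaluation is total: any variable absent from the environment counts
    as 0, and the result is coerced to a boolean.
    """

    text: str
    root: Node

    def evaluate(self, env: Mapping[str, float]) -> bool:
        return _evaluate(self.root, env) != 0

    def variables(self) -> set[str]:
        return _variables(self.root)


# -- tokenizer + recursive-descent parser ---------------------------------

_QUOTE_TRANSLATION = str.maketrans({"“": '"', "”": '"',
                                    "‘": "'", "’": "'"})

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<var>\[\s*(?P<varname>[A-Za-z_][A-Za-z0-9_]*)\s*\])
  | (?P<qnum>"(?P<qval>-?\d+(\.\d+)?)"|'(?P<qval2>-?\d+(\.\d+)?)')
  | (?P<num>-?\d+(\.\d+)?)
  | (?P<kw>\b(?:and|or)\b)
  | (?P<op>[=<+()])
    """,
    re.VERBOSE | re.IGNORECASE,
)


@dataclass(frozen=True)
class _Token:
    kind: str  # VAR NUM AND OR OP END
    value: object
    pos: int


def _tokenize(text: str) -> Iterator[_Token]:
    pos = 0
    n = len(text)
    while pos < n:
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ConditionSyntaxError(f"unexpected character {text[pos]!r}", pos)
        if m.lastgroup != "ws":
            if m.group("var"):
                yield _Token("VAR", m.group("varname"), pos)
            elif m.group("qnum"):
                raw = m.group("qval") or m.group("qval2")
                yield _Token("NUM", float(raw), pos)
            elif m.group("num"):
                yield _Token("NUM", float(m.group("num")), pos)
            elif m.group("kw"):
                yield _Token(m.group("kw").lower().upper(), None, pos)
            else:
                yield _Token("OP", m.group("op"), pos)
        pos = m.end()
    yield _Token("END", None, n)


class _Parser:
    def __init__(self, tokens: list[_Token]):
        self.tokens = tokens
        self.i = 0

    @property
    def cur(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        tok = self.cur
        self.i += 1
        return tok

    def expect_op(self, op: str) -> None:
        tok = self.cur
        if tok.kind != "OP" or tok.value != op:
            raise ConditionSyntaxError(f"expected {op!r}", tok.pos)
        self.advance()

    def parse(self) -> Node:
        node = self.or_expr()
        if self.cur.kind != "END":
            raise ConditionSyntaxError("unexpected trailing input", self.cur.pos)
        return node

    def or_expr(self) -> Node:
        node = self.and_expr()
        while self.cur.kind == "OR":
            self.advance()
            node = BinOp("or", node, self.and_expr())
        return node

    def and_expr(self) -> Node:
        node = self.comparison()
        while self.cur.kind == "AND":
            self.advance()
            node = BinOp("and", node, self.comparison())
        return node

    def comparison(self) -> Node:
        node = self.sum()
        if self.cur.kind == "OP" and self.cur.value in ("=", "<"):
            op = str(self.advance().value)
            node = BinOp(op, node, self.sum())
        return node

    def sum(self) -> Node:
        node = self.primary()
        while self.cur.kind == "OP" and self.cur.value == "+":
            self.advance()
            node = BinOp("+", node, self.primary())
        return node

    def primary(self) -> Node:
        tok = self.cur
        if tok.kind == "OP" and tok.value == "(":
            self.advance()
            node = self.or_expr()
            self.expect_op(")")
            return node
        if tok.kind == "VAR":
            self.advance()
            return Var(str(tok.value))
        if tok.kind == "NUM":
            self.advance()
            return Lit(float(tok.value))  # type: ignore[arg-type]
        raise ConditionSyntaxError("expected '(', a [variable] or a number", tok.pos)


@lru_cache(maxsize=256)
def parse_condition(text: str) -> ConditionExpr:
    """Parse a survey-queue condition; curly quotes are normalized first.

    Raises :class:`ConditionSyntaxError` with the character position on
    malformed input.
    """
    normalized = text.translate(_QUOTE_TRANSLATION)
    tokens = list(_tokenize(normalized))
    root = _Parser(tokens).parse()
    return ConditionExpr(text=text, root=root)


# -- randomization and navigation -----------------------------------------

def draw_mod6(rng: np.random.Generator) -> int:
    """Uniform draw on {1,…,6} selecting one of the six task orders."""
    return int(rng.integers(1, 7))


def _environment(project: ProjectDef, record: SessionRecord) -> dict[str, float]:
    env: dict[str, float] = {}
    for key, value in record.field_values.items():
        try:
            env[key] = float(value)
        except (TypeError, ValueError):
            continue
    for inst in project.instruments:
        env[inst.completion_flag_var] = float(record.completion_flags.get(inst.name, 0))
    env[project.randomization_var] = float(record.mod6 or 0)
    return env


def eligible_instruments(project: ProjectDef, record: SessionRecord) -> list[str]:
    """Names of the queued instruments whose condition holds and whose own
    completion flag is still 0, in declaration order.

    Requires the preliminary instrument to be complete (flag 2) — before
    that the queue is not evaluated at all.
    """
    prelim = project.preliminary
    if record.completion_flags.get(prelim.name, 0) != 2:
        raise QueueError("preliminary instrument must be complete (flag 2) first")
    env = _environment(project, record)
    out = []
    for inst in project.queued_instruments:
        if record.completion_flags.get(inst.name, 0) != 0:
            continue
        text = project.queue_conditions.get(inst.name)
        if text is None or parse_condition(text).evaluate(env):
            out.append(inst.name)
    return out


def next_instrument(project: ProjectDef, record: SessionRecord) -> Optional[str]:
    """The unique eligible instrument ("auto start" navigation), or
    ``None`` once every queued instrument is complete.

    Raises :class:`AmbiguousQueueError` on more than one eligible
    instrument and :class:`QueueDeadlockError` when none is eligible but
    some remain incomplete — both indicate broken user-supplied conditions.
    """
    eligible = eligible_instruments(project, record)
    if len(eligible) > 1:
        raise AmbiguousQueueError(
            f"{len(eligible)} instruments simultaneously eligible: {eligible}"
        )
    if eligible:
        return eligible[0]
    incomplete = [
        i.name
        for i in project.queued_instruments
        if record.completion_flags.get(i.name, 0) == 0
    ]
    if incomplete:
        raise QueueDeadlockError(f"no instrument eligible; incomplete: {incomplete}")
    return None


def order_for(mod6: int, project: ProjectDef) -> tuple[str, ...]:
    """Task order induced by a draw: simulate sequential completion,
    setting each finished flag to 2, and return the visited sequence."""
    if not 1 <= mod6 <= 6:
        raise ValueError("mod6 must lie in 1..6")
    record = SessionRecord(record_id="_probe", mod6=mod6)
    record.completion_flags[project.preliminary.name] = 2
    order: list[str] = []
    while (name := next_instrument(project, record)) is not None:
        order.append(name)
        record.completion_flags[name] = 2
    return tuple(order)


def queue_orders(project: ProjectDef) -> dict[int, tuple[str, ...]]:
    """Mapping draw -> induced order, for all six draws."""
    return {m: order_for(m, project) for m in range(1, 7)}


def uniqueness_table(project: ProjectDef) -> "pd.DataFrame":  # noqa: F821
    """Step-by-step eligibility proof over every reachable flag state.

    One row per (draw, step): which instruments are complete, which are
    eligible, and whether exactly one is.  Used by the ``verify-queue``
    CLI command; ``all(table['unique'])`` certifies the conditions.
    """
    import pandas as pd

    rows = []
    for m in range(1, 7):
        record = SessionRecord(record_id="_probe", mod6=m)
        record.completion_flags[project.preliminary.name] = 2
        for step in range(1, len(project.queued_instruments) + 1):
            eligible = eligible_instruments(project, record)
            done = [
                i.name
                for i in project.queued_instruments
                if record.completion_flags.get(i.name, 0) == 2
            ]
            rows.append(
                {
                    "mod6": m,
                    "step": step,
                    "completed": " ".join(done) or "-",
                    "eligible": " ".join(eligible) or "-",
                    "n_eligible": len(eligible),
                    "unique": len(eligible) == 1,
                }
            )
            if len(eligible) != 1:
                break
            record.completion_flags[eligible[0]] = 2
    return pd.DataFrame(rows)
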