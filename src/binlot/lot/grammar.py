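"""Expression grammar for binary sequences built from stay/flip instructions.

An expression is one of:

* :class:`Atom` -- a single emitting instruction.  ``STAY`` emits the
  current state, ``FLIP`` toggles the state and emits the new one.
* :class:`Repeat` -- ``count`` executions of a body expression, optionally
  followed (after *every* repetition, including the last) by a silent
  transform instruction that changes the state without emitting.
* :class:`Concat` -- two or more expressions executed left to right,
  threading the state.

The description length of an expression is a weighted sum of its
instruction occurrences (emitting atoms and silent transforms alike) plus
a digit cost for every repetition count, see :class:`CostScheme`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

__all__ = [
    "Instruction",
    "Atom",
    "Repeat",
    "Concat",
    "Expression",
    "CostScheme",
    "DEFAULT_SCHEME",
    "STAY",
    "FLIP",
    "decimal_digit_cost",
    "evaluate",
    "expression_cost",
    "expression_depth",
    "emission_length",
    "repeat_cuts",
    "is_chunk_preserving",
]


class Instruction(enum.Enum):
    """The two primitive instructions of the language."""

    STAY = "+0"
    FLIP = "b"

    def apply(self, state: str) -> str:
        if self is Instruction.STAY:
            return state
        return "B" if state == "A" else "A"


STAY = Instruction.STAY
FLIP = Instruction.FLIP


@dataclass(frozen=True)
class Atom:
    instr: Instruction

    def __post_init__(self) -> None:
        if not isinstance(self.instr, Instruction):
            raise TypeError(f"Atom instruction must be an Instruction, got {self.instr!r}")


@dataclass(frozen=True)
class Repeat:
    body: "Expression"
    count: int
    transform: Optional[Instruction] = None

    def __post_init__(self) -> None:
        if not isinstance(self.count, int) or self.count < 1:
            raise ValueError(f"repeat count must be an integer >= 1, got {self.count!r}")
        if self.transform is not None and not isinstance(self.transform, Instruction):
            raise TypeError("transform must be an Instruction or None")


@dataclass(frozen=True)
class Concat:
    terms: tuple

    def __init__(self, *terms: "Expression") -> None:
        # accept Concat(a, b, ...) or Concat((a, b, ...)); nested concatenations
        # flatten so that rendering round-trips structurally.
        if len(terms) == 1 and isinstance(terms[0], (tuple, list)):
            terms = tuple(terms[0])
        flat: list = []
        for t in terms:
            if isinstance(t, Concat):
                flat.extend(t.terms)
            else:
                flat.append(t)
        if len(flat) < 2:
            raise ValueError("Concat requires at least 2 terms")
        object.__setattr__(self, "terms", tuple(flat))


Expression = Union[Atom, Repeat, Concat]


def decimal_digit_cost(n: int) -> int:
    """Cost of writing a repetition count: ceil(log10(n)), with n = 1 free.

    Computed with integer arithmetic so that exact powers of ten are not
    subject to floating-point rounding (n = 10 costs 1).
    """
    if n < 1:
        raise ValueError("count must be >= 1")
    d, p = 0, 1
    while p < n:
        d += 1
        p *= 10
    return d


@dataclass(frozen=True)
class CostScheme:
    """Weights defining the description length of an expression."""

    instruction_weight: float = 2
    digit_cost: Callable[[int], float] = field(default=decimal_digit_cost)


DEFAULT_SCHEME = CostScheme()


def _check_state(state: str) -> None:
    if state not in ("A", "B"):
        raise ValueError(f"state must be 'A' or 'B', got {state!r}")


def evaluate(expr: Expression, start_state: str = "A") -> tuple[str, str]:
    """Run ``expr`` from ``start_state``; return ``(emitted, end_state)``.

    Silent transforms apply after every repetition (including the last), so
    the end state reflects them even though they emit nothing.
    """
    _check_state(start_state)
    out: list[str] = []
    end = _run(expr, start_state, out)
    return "".join(out), end


def _run(expr: Expression, state: str, out: list[str]) -> str:
    if isinstance(expr, Atom):
        state = expr.instr.apply(state)
        out.append(state)
        return state
    if isinstance(expr, Repeat):
        for _ in range(expr.count):
            state = _run(expr.body, state, out)
            if expr.transform is not None:
                state = expr.transform.apply(state)
        return state
    if isinstance(expr, Concat):
        for term in expr.terms:
            state = _run(term, state, out)
        return state
    raise TypeError(f"not an expression: {expr!r}")


def expression_cost(expr: Expression, scheme: CostScheme = DEFAULT_SCHEME) -> float:
    """Weighted description length: instructions (emitting and silent) plus digits."""
    if isinstance(expr, Atom):
        return scheme.instruction_weight
    if isinstance(expr, Repeat):
        cost = expression_cost(expr.body, scheme) + scheme.digit_cost(expr.count)
        if expr.transform is not None:
            cost += scheme.instruction_weight
        return cost
    if isinstance(expr, Concat):
        return sum(expression_cost(t, scheme) for t in expr.terms)
    raise TypeError(f"not an expression: {expr!r}")


def expression_depth(expr: Expression) -> int:
    """Maximum number of Repeat nodes on a root-to-leaf path (min 1)."""
    return max(1, _depth(expr))


def _depth(expr: Expression) -> int:
    if isinstance(expr, Atom):
        return 0
    if isinstance(expr, Repeat):
        return 1 + _depth(expr.body)
    if isinstance(expr, Concat):
        return max(_depth(t) for t in expr.terms)
    raise TypeError(f"not an expression: {expr!r}")


def emission_length(expr: Expression) -> int:
    """Number of items the expression emits (independent of start state)."""
    if isinstance(expr, Atom):
        return 1
    if isinstance(expr, Repeat):
        return expr.count * emission_length(expr.body)
    if isinstance(expr, Concat):
        return sum(emission_length(t) for t in expr.terms)
    raise TypeError(f"not an expression: {expr!r}")


def repeat_cuts(expr: Expression) -> set[int]:
    """Emission positions where a multi-item repeated block opens or closes.

    A Repeat whose body emits >= 2 items contributes the boundaries between
    consecutive repetitions and the two outer edges of its emission span.
    Repeats of a single-item body (run builders) are exempt.  Positions are
    offsets into the emitted sequence (a cut at p falls between items p-1
    and p).
    """
    cuts: set[int] = set()
    _collect_cuts(expr, 0, cuts)
    return cuts


def _collect_cuts(expr: Expression, offset: int, cuts: set[int]) -> int:
    if isinstance(expr, Atom):
        return offset + 1
    if isinstance(expr, Repeat):
        block = emission_length(expr.body)
        if block >= 2:
            for k in range(expr.count + 1):
                cuts.add(offset + k * block)
        pos = offset
        for _ in range(expr.count):
            pos = _collect_cuts(expr.body, pos, cuts)
        return pos
    if isinstance(expr, Concat):
        for term in expr.terms:
            offset = _collect_cuts(term, offset, cuts)
        return offset
    raise TypeError(f"not an expression: {expr!r}")


def is_chunk_preserving(expr: Expression, start_state: str = "A") -> bool:
    """True if no repeated-block boundary splits a run of identical items.

    Checks, directly on the expression tree and its emission, that every
    cut from :func:`repeat_cuts` that falls strictly inside the emitted
    sequence separates two different items (no "A][A" or "B][B").
    """
    emitted, _ = evaluate(expr, start_state)
    n = len(emitted)
    for p in repeat_cuts(expr):
        if 0 < p < n and emitted[p - 1] == emitted[p]:
            return False
    return True
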