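"""Surface notation for expressions.

Grammar::

    expr := term ("," expr)?
    term := "+0" | "b" | "[" expr "]" "^" int ("<" ("+0" | "b") ">")?

Examples: ``[+0]^4<b>`` (four stays, flipping the state after each one),
``[[+0]^8]^2<b>``, ``+0,b,+0``.  Whitespace around tokens is ignored.
"""

from __future__ import annotations

from .grammar import Atom, Concat, Expression, Instruction, Repeat

__all__ = ["render", "parse_notation", "NotationError"]


class NotationError(ValueError):
    """Malformed notation; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def render(expr: Expression) -> str:
    """Serialize an expression; inverse of :func:`parse_notation`."""
    if isinstance(expr, Atom):
        return expr.instr.value
    if isinstance(expr, Repeat):
        text = f"[{render(expr.body)}]^{expr.count}"
        if expr.transform is not None:
            text += f"<{expr.transform.value}>"
        return text
    if isinstance(expr, Concat):
        return ",".join(render(t) for t in expr.terms)
    raise TypeError(f"not an expression: {expr!r}")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, message: str) -> NotationError:
        return NotationError(message, self.pos)

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def expect(self, token: str) -> None:
        self.skip_ws()
        if not self.text.startswith(token, self.pos):
            raise self.error(f"expected {token!r}")
        self.pos += len(token)

    def instruction(self) -> Instruction:
        self.skip_ws()
        if self.text.startswith("+0", self.pos):
            self.pos += 2
            return Instruction.STAY
        if self.peek() == "b":
            self.pos += 1
            return Instruction.FLIP
        raise self.error("expected instruction '+0' or 'b'")

    def integer(self) -> int:
        self.skip_ws()
        start = self.pos
        while self.peek().isdigit():
            self.pos += 1
        if self.pos == start:
            raise self.error("expected an integer")
        return int(self.text[start:self.pos])

    def term(self) -> Expression:
        self.skip_ws()
        if self.peek() == "[":
            self.pos += 1
            body = self.expr()
            self.expect("]")
            self.expect("^")
            count = self.integer()
            if count < 1:
                raise self.error("repeat count must be >= 1")
            transform = None
            self.skip_ws()
            if self.peek() == "<":
                self.pos += 1
                transform = self.instruction()
                self.expect(">")
            return Repeat(body, count, transform)
        return Atom(self.instruction())

    def expr(self) -> Expression:
        terms = [self.term()]
        while True:
            self.skip_ws()
            if self.peek() != ",":
                break
            self.pos += 1
            terms.append(self.term())
        if len(terms) == 1:
            return terms[0]
        return Concat(*terms)


def parse_notation(text: str) -> Expression:
    """Parse surface notation into an expression tree.

    Raises :class:`NotationError` (with position) on malformed input.
    """
    parser = _Parser(text)
    expr = parser.expr()
    parser.skip_ws()
    if parser.pos != len(text):
        raise parser.error("unexpected trailing text")
    return expr
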