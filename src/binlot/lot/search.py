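"""Exact minimal-description search and brute-force enumeration.

:func:`minimal_description` finds, by dynamic programming over substring
spans and start/end states, the cheapest grammar expressions generating a
sequence (optionally restricted to chunk-preserving expressions whose
repeated-block boundaries never split a run of identical items).

:func:`enumerate_descriptions` is an independent, budget-limited generator
of *all* expressions up to a cost bound; it serves as a brute-force oracle
for the minimizer and is only practical for short sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

from .grammar import (
    DEFAULT_SCHEME,
    Atom,
    Concat,
    CostScheme,
    Expression,
    Instruction,
    Repeat,
    expression_depth,
    is_chunk_preserving,
)
from .notation import render
from .sequences import canonicalize, validate_sequence

__all__ = [
    "EncodingResult",
    "minimal_description",
    "enumerate_descriptions",
    "EnumerationBudgetError",
]

_INF = float("inf")


@dataclass(frozen=True)
class EncodingResult:
    """Outcome of the minimal-description search.

    Every expression in ``minimal_expressions`` evaluates from state A to
    exactly ``sequence`` and costs ``complexity``; no legal (and, if
    ``chunk_preserving``, chunk-preserving) expression is cheaper.
    ``depth`` is the minimum hierarchical depth among the tied minima.
    """

    sequence: str
    complexity: float
    minimal_expressions: tuple
    depth: int
    chunk_preserving: bool


class EnumerationBudgetError(RuntimeError):
    """The brute-force enumeration exceeded its node budget."""


def _wrap(terms: tuple) -> Expression:
    return terms[0] if len(terms) == 1 else Concat(*terms)


class _Search:
    """Span DP.  States are 0 (item A) and 1 (item B).

    ``U[i, j]`` holds the cheapest *single term* (atom or repeat) and
    ``E[i, j]`` the cheapest expression (term sequence) emitting
    ``seq[i:j)``, each as a 2x2 matrix over (start state, end state).
    Expressions that only add silent no-ops -- repeats with count 1 and no
    transform, or stay transforms -- are cost-redundant and excluded, which
    keeps the set of tied minima finite.
    """

    def __init__(self, seq: str, scheme: CostScheme, chunk: bool):
        self.seq01 = [0 if c == "A" else 1 for c in seq]
        self.n = len(seq)
        self.w = scheme.instruction_weight
        self.dc = scheme.digit_cost
        self.chunk = chunk
        self.U: dict = {}
        self.E: dict = {}
        self._solve()

    # -- cost tables ---------------------------------------------------

    def _repeat_options(self, i: int, j: int) -> Iterator[tuple[int, int, int, int]]:
        """Yield (L, nrep, delta, tau) consistent with seq[i:j) block structure."""
        seq01, n = self.seq01, self.n
        span = j - i
        for L in range(1, span // 2 + 1):
            if span % L:
                continue
            nrep = span // L
            eq = all(seq01[i + k] == seq01[i + k % L] for k in range(L, span))
            alt = all(seq01[i + k] == seq01[i + k % L] ^ (k // L & 1) for k in range(L, span))
            if not (eq or alt):
                continue
            if self.chunk and L >= 2:
                ok = all(seq01[i + k * L - 1] != seq01[i + k * L] for k in range(1, nrep))
                if i > 0:
                    ok = ok and seq01[i - 1] != seq01[i]
                if j < n:
                    ok = ok and seq01[j - 1] != seq01[j]
                if not ok:
                    continue
            for delta in (0, 1):
                for tau in (0, 1):
                    if (delta ^ tau) == (0 if eq else 1):
                        yield L, nrep, delta, tau

    def _solve(self) -> None:
        seq01, n, w = self.seq01, self.n, self.w
        for span in range(1, n + 1):
            for i in range(n - span + 1):
                j = i + span
                U = [[_INF, _INF], [_INF, _INF]]
                E = [[_INF, _INF], [_INF, _INF]]
                if span == 1:
                    for s in (0, 1):
                        U[s][seq01[i]] = w
                for L, nrep, delta, tau in self._repeat_options(i, j):
                    extra = w * tau + self.dc(nrep)
                    tshift = nrep * (delta ^ tau) & 1
                    for s in (0, 1):
                        body = self.E[i, i + L][s][s ^ delta]
                        if body + extra < U[s][s ^ tshift]:
                            U[s][s ^ tshift] = body + extra
                for s in (0, 1):
                    for t in (0, 1):
                        E[s][t] = U[s][t]
                for k in range(i + 1, j):
                    Uik, Ekj = self.U[i, k], self.E[k, j]
                    for s in (0, 1):
                        for m in (0, 1):
                            if Uik[s][m] is _INF:
                                continue
                            for t in (0, 1):
                                c = Uik[s][m] + Ekj[m][t]
                                if c < E[s][t]:
                                    E[s][t] = c
                self.U[i, j] = U
                self.E[i, j] = E

    # -- reconstruction ------------------------------------------------

    def unit_exprs(self, i: int, j: int, s: int, t: int, memo: dict) -> list:
        key = ("U", i, j, s, t)
        if key in memo:
            return memo[key]
        target = self.U[i, j][s][t]
        out: list = []
        if target is not _INF:
            if j - i == 1:
                instr = Instruction.STAY if self.seq01[i] == s else Instruction.FLIP
                out.append(Atom(instr))
            for L, nrep, delta, tau in self._repeat_options(i, j):
                extra = self.w * tau + self.dc(nrep)
                if s ^ (nrep * (delta ^ tau) & 1) != t:
                    continue
                if self.E[i, i + L][s][s ^ delta] + extra != target:
                    continue
                transform = Instruction.FLIP if tau else None
                for body_terms in self.exprs(i, i + L, s, s ^ delta, memo):
                    out.append(Repeat(_wrap(body_terms), nrep, transform))
        memo[key] = out
        return out

    def exprs(self, i: int, j: int, s: int, t: int, memo: dict) -> list:
        """All minimal term tuples for span [i, j) from state s to state t."""
        key = ("E", i, j, s, t)
        if key in memo:
            return memo[key]
        target = self.E[i, j][s][t]
        out: list = []
        if target is not _INF:
            if self.U[i, j][s][t] == target:
                out.extend((u,) for u in self.unit_exprs(i, j, s, t, memo))
            for k in range(i + 1, j):
                for m in (0, 1):
                    if self.U[i, k][s][m] + self.E[k, j][m][t] != target:
                        continue
                    rests = self.exprs(k, j, m, t, memo)
                    for u in self.unit_exprs(i, k, s, m, memo):
                        for rest in rests:
                            out.append((u,) + rest)
        memo[key] = out
        return out


def minimal_description(
    seq: str,
    scheme: CostScheme = DEFAULT_SCHEME,
    chunk_preserving: bool = False,
    max_len: int = 24,
) -> EncodingResult:
    """Exact minimum description length of ``seq`` (canonicalized first).

    Returns the minimum cost over all grammar expressions evaluating from
    state A to the canonical sequence, all tied minimal expressions
    (structurally deduplicated, sorted by their rendered notation) and the
    minimum hierarchical depth among them.  With ``chunk_preserving``, the
    minimization is restricted to expressions whose repeated-block
    boundaries never fall inside a run of identical items.
    """
    validate_sequence(seq)
    if len(seq) > max_len:
        raise ValueError(f"sequence length {len(seq)} exceeds the bound {max_len}")
    canonical = canonicalize(seq)
    search = _Search(canonical, scheme, chunk_preserving)
    n = len(canonical)
    full = search.E[0, n][0]
    complexity = min(full)
    if complexity is _INF:  # cannot happen: the flat encoding always exists
        raise RuntimeError(f"no expression found for {canonical!r}")
    memo: dict = {}
    expressions: dict[str, Expression] = {}
    for t in (0, 1):
        if full[t] == complexity:
            for terms in search.exprs(0, n, 0, t, memo):
                expr = _wrap(terms)
                expressions[render(expr)] = expr
    ordered = tuple(expressions[k] for k in sorted(expressions))
    depth = min(expression_depth(e) for e in ordered)
    return EncodingResult(canonical, complexity, ordered, depth, chunk_preserving)


# -- brute-force enumeration ------------------------------------------


class _Budget:
    def __init__(self, limit: int):
        self.limit = limit
        self.used = 0

    def tick(self) -> None:
        self.used += 1
        if self.used > self.limit:
            raise EnumerationBudgetError(
                f"enumeration exceeded the {self.limit}-node budget"
            )


def _enum_units(maxlen, budget_cost, state, scheme, budget):
    """Yield (expr, emission tuple, end state, cost) for single terms.

    Structurally redundant silent no-ops (count-1 repeats without a
    transform, stay transforms) are skipped; they never change emission or
    lower cost.
    """
    w = scheme.instruction_weight
    if maxlen < 1 or budget_cost < w:
        return
    for instr in (Instruction.STAY, Instruction.FLIP):
        emitted = state if instr is Instruction.STAY else state ^ 1
        budget.tick()
        yield Atom(instr), (emitted,), emitted, w
    # repeats with count >= 2
    for body, bem, bend, bcost in _enum_exprs(
        maxlen // 2, budget_cost - scheme.digit_cost(2), state, scheme, budget
    ):
        L = len(bem)
        delta = bend ^ state
        for tau in (0, 1):
            step = delta ^ tau
            base = bcost + w * tau
            count = 2
            while L * count <= maxlen:
                cost = base + scheme.digit_cost(count)
                if cost > budget_cost:
                    break
                emission: list[int] = []
                s = state
                for _ in range(count):
                    emission.extend(bem if s == state else tuple(x ^ 1 for x in bem))
                    s ^= step
                budget.tick()
                transform = Instruction.FLIP if tau else None
                yield Repeat(_wrap(body), count, transform), tuple(emission), s, cost
                count += 1
    # count-1 repeat with a flip transform: silent state change
    for body, bem, bend, bcost in _enum_exprs(
        maxlen, budget_cost - w, state, scheme, budget
    ):
        budget.tick()
        yield Repeat(_wrap(body), 1, Instruction.FLIP), bem, bend ^ 1, bcost + w


def _enum_exprs(maxlen, budget_cost, state, scheme, budget):
    """Yield (term tuple, emission, end state, cost) for term sequences."""
    for unit, em, end, cost in _enum_units(maxlen, budget_cost, state, scheme, budget):
        yield (unit,), em, end, cost
        for terms, em2, end2, cost2 in _enum_exprs(
            maxlen - len(em), budget_cost - cost, end, scheme, budget
        ):
            yield (unit,) + terms, em + em2, end2, cost + cost2


def enumerate_descriptions(
    seq: str,
    max_cost: float,
    chunk_preserving: bool = False,
    scheme: CostScheme = DEFAULT_SCHEME,
    max_nodes: int = 20_000_000,
) -> list[tuple[Expression, float]]:
    """All expressions with cost <= ``max_cost`` generating ``seq`` from A.

    Exhaustive generate-and-filter (no shared machinery with
    :func:`minimal_description`); exponential, intended for short
    sequences.  Raises :class:`EnumerationBudgetError` when more than
    ``max_nodes`` candidate expressions are visited.
    """
    validate_sequence(seq)
    canonical = canonicalize(seq)
    target = tuple(0 if c == "A" else 1 for c in canonical)
    budget = _Budget(max_nodes)
    out = []
    for terms, em, _end, cost in _enum_exprs(len(target), max_cost, 0, scheme, budget):
        if em != target:
            continue
        expr = _wrap(terms)
        if chunk_preserving and not is_chunk_preserving(expr):
            continue
        out.append((expr, cost))
    return out
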