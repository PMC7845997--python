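"""Rival complexity measures for binary sequences.

Six measures raced against the description-length complexity: run-based
chunk complexity, pair entropy, Lempel-Ziv (LZ78) vocabulary size, number
of subsymmetries, change complexity, and an external lookup table of
algorithmic complexity values for short strings.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .lot.sequences import flip, validate_sequence

__all__ = [
    "RunDecomposition",
    "run_lengths",
    "chunk_complexity",
    "pair_entropy",
    "lz78_complexity",
    "subsymmetries",
    "change_complexity",
    "AcssTable",
    "acss_lookup",
    "metrics_table",
]


@dataclass(frozen=True)
class RunDecomposition:
    """Maximal runs of identical items, in order."""

    runs: tuple  # of (item, length)

    @property
    def K(self) -> int:
        return len(self.runs)

    @property
    def lengths(self) -> tuple:
        return tuple(length for _, length in self.runs)


def run_lengths(seq: str) -> RunDecomposition:
    validate_sequence(seq)
    runs = []
    item, count = seq[0], 1
    for c in seq[1:]:
        if c == item:
            count += 1
        else:
            runs.append((item, count))
            item, count = c, 1
    runs.append((item, count))
    return RunDecomposition(tuple(runs))


def chunk_complexity(seq: str) -> float:
    """Sum of log2(1 + L_i) over the run decomposition."""
    return sum(math.log2(1 + L) for L in run_lengths(seq).lengths)


def pair_entropy(seq: str) -> float:
    """Shannon entropy of the four pair outcomes (AA, AB, BA, BB).

    Pair probabilities are p(X, Y) = p(X) * p(Y|X), with p(X) the item
    frequency over the whole sequence and p(Y|X) the maximum-likelihood
    transition probability from one linear presentation.  Terms with zero
    probability contribute 0 (the 0*log2(0) = 0 convention); an item that
    never occurs as a predecessor contributes nothing.
    """
    validate_sequence(seq)
    if len(seq) < 2:
        raise ValueError("pair entropy needs a sequence of length >= 2")
    n = len(seq)
    marg = {x: seq.count(x) / n for x in "AB"}
    out_counts = {x: sum(1 for c in seq[:-1] if c == x) for x in "AB"}
    trans = {(x, y): 0 for x in "AB" for y in "AB"}
    for a, b in zip(seq, seq[1:]):
        trans[a, b] += 1
    h = 0.0
    for x in "AB":
        if out_counts[x] == 0:
            continue
        for y in "AB":
            p_cond = trans[x, y] / out_counts[x]
            p_pair = marg[x] * p_cond
            if p_pair > 0:
                h -= p_pair * (math.log2(marg[x]) + math.log2(p_cond))
    return h


def lz78_complexity(seq: str, count_incomplete_final: bool = True) -> int:
    """Vocabulary size of the left-to-right incremental (LZ78) parse.

    Each phrase is the shortest prefix of the remaining input not yet in
    the vocabulary.  If the scan ends in the middle of a phrase (the
    remaining suffix is already known), that incomplete phrase counts as
    one entry unless ``count_incomplete_final`` is false.
    """
    validate_sequence(seq)
    vocab: set[str] = set()
    phrase = ""
    count = 0
    for c in seq:
        phrase += c
        if phrase not in vocab:
            vocab.add(phrase)
            count += 1
            phrase = ""
    if phrase and count_incomplete_final:
        count += 1
    return count


def subsymmetries(seq: str) -> int:
    """Number of contiguous palindromic substrings of length >= 2.

    Counted by expanding around each of the 2n - 1 palindrome centers.
    """
    validate_sequence(seq)
    n = len(seq)
    total = 0
    for center in range(2 * n - 1):
        left, right = center // 2, center // 2 + center % 2
        if left == right:  # odd length; start from length 3
            left, right = left - 1, right + 1
        while left >= 0 and right < n and seq[left] == seq[right]:
            total += 1
            left -= 1
            right += 1
    return total


def change_complexity(seq: str) -> float:
    """Cumulative change over all window lengths of a binary sequence.

    The absolute-difference operator is applied recursively, producing one
    shorter 0/1 profile per level; level l holds the change parity of the
    windows of length l + 1.  The complexity is the sum over levels of the
    mean change, so a constant sequence scores 0 and the score is invariant
    under relabeling (only transitions enter the first profile).
    """
    validate_sequence(seq)
    if len(seq) < 2:
        raise ValueError("change complexity needs a sequence of length >= 2")
    x = np.array([0 if c == "A" else 1 for c in seq], dtype=np.int64)
    total = 0.0
    while x.size > 1:
        x = np.abs(np.diff(x))
        total += float(x.mean())
    return total


@dataclass(frozen=True)
class AcssTable:
    """External lookup table of algorithmic-complexity values.

    Values approximate Kolmogorov complexity of short strings via the
    output distribution of small universal Turing machines; they are
    published elsewhere and only loaded here, never computed.
    """

    values: dict = field(default_factory=dict)
    provenance: str = ""

    @classmethod
    def from_csv(cls, path) -> "AcssTable":
        """Load a two-column CSV ``pattern,value`` (header optional)."""
        path = Path(path)
        values: dict[str, float] = {}
        with path.open(newline="") as fh:
            for lineno, row in enumerate(csv.reader(fh), start=1):
                if not row or not row[0].strip():
                    continue
                pattern = row[0].strip()
                if lineno == 1 and not set(pattern) <= set("AB"):
                    continue  # header row
                if len(row) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'pattern,value'")
                if not set(pattern) <= set("AB"):
                    raise ValueError(f"{path}:{lineno}: bad pattern {pattern!r}")
                try:
                    values[pattern] = float(row[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad value {row[1]!r}") from exc
        return cls(values, provenance=str(path))

    def lookup(self, seq: str) -> Optional[float]:
        """Value for the pattern under either labeling, or None if absent."""
        validate_sequence(seq)
        if seq in self.values:
            return self.values[seq]
        return self.values.get(flip(seq))


def acss_lookup(seq: str, table: AcssTable) -> Optional[float]:
    return table.lookup(seq)


def _acss_or_nan(table: Optional[AcssTable], pattern: str) -> float:
    if table is None:
        return float("nan")
    value = table.lookup(pattern)
    return float("nan") if value is None else value


def metrics_table(patterns, acss: Optional[AcssTable] = None):
    """One row of every complexity measure per pattern.

    Columns: pattern, length, lot, lot_chunk, chunk, entropy, lz, subsym,
    change, acss (NaN when not in the table or none given), period, depth.
    """
    import pandas as pd

    from .lot.search import minimal_description
    from .lot.sequences import canonicalize, period

    rows = []
    for pattern in patterns:
        pattern = canonicalize(pattern)
        plain = minimal_description(pattern)
        chunked = minimal_description(pattern, chunk_preserving=True)
        rows.append(
            {
                "pattern": pattern,
                "length": len(pattern),
                "lot": plain.complexity,
                "lot_chunk": chunked.complexity,
                "chunk": chunk_complexity(pattern),
                "entropy": pair_entropy(pattern) if len(pattern) > 1 else np.nan,
                "lz": lz78_complexity(pattern),
                "subsym": subsymmetries(pattern),
                "change": change_complexity(pattern) if len(pattern) > 1 else np.nan,
                "acss": _acss_or_nan(acss, pattern),
                "period": period(pattern),
                "depth": plain.depth,
            }
        )
    return pd.DataFrame(rows)
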