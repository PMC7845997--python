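"""Shannon surprise of deviant items under fixed transition probabilities.

The standard sequence is assumed fully learned, so transition
probabilities are maximum-likelihood estimates from one linear
presentation (no wrap-around) and stay fixed.  The surprise of observing
an item given its predecessor is the negative base-2 log of its transition
probability; exact-zero probabilities are padded with a small constant
(default 0.01, capping surprise near 6.64 bits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .lot.sequences import flip, validate_sequence

__all__ = [
    "TransitionModel",
    "DeviantEvent",
    "estimate_transitions",
    "surprise",
    "deviant_surprise",
    "mean_deviant_surprise",
    "DEFAULT_PADDING",
]

DEFAULT_PADDING = 0.01


@dataclass(frozen=True)
class TransitionModel:
    """First-order transition probabilities and item frequencies.

    ``p_given[(prev, nxt)]`` is the ML probability of ``nxt`` following
    ``prev``; pairs whose predecessor never occurs before another item are
    absent (undefined), not zero.
    """

    p_given: dict
    item_freq: dict
    counts: dict

    def conditional(self, prev: str, nxt: str) -> Optional[float]:
        return self.p_given.get((prev, nxt))


def estimate_transitions(seq: str) -> TransitionModel:
    """Count the len - 1 adjacent pairs of one presentation of ``seq``."""
    validate_sequence(seq)
    if len(seq) < 2:
        raise ValueError("need at least 2 items to estimate transitions")
    counts = {(a, b): 0 for a in "AB" for b in "AB"}
    for a, b in zip(seq, seq[1:]):
        counts[a, b] += 1
    p_given = {}
    for prev in "AB":
        total = counts[prev, "A"] + counts[prev, "B"]
        if total:
            for nxt in "AB":
                p_given[prev, nxt] = counts[prev, nxt] / total
    item_freq = {x: seq.count(x) / len(seq) for x in "AB"}
    return TransitionModel(p_given, item_freq, counts)


def surprise(
    model: TransitionModel,
    prev_item: str,
    observed_item: str,
    padding: float = DEFAULT_PADDING,
) -> float:
    """-log2 of p(observed | prev); zero probabilities padded to ``padding``."""
    p = model.conditional(prev_item, observed_item)
    if p is None:
        if padding is None or padding <= 0:
            raise ValueError(
                f"no transition recorded out of {prev_item!r} and no padding rule"
            )
        p = 0.0
    if p == 0.0:
        if padding is None or padding <= 0:
            raise ValueError("zero-probability transition and no padding rule")
        p = padding
    return -math.log2(p)


@dataclass(frozen=True)
class DeviantEvent:
    """A deviant item replacing the original one at a 1-based position."""

    sequence: str
    position: int
    deviant_item: str
    deviant_type: str = "sequence"

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if not 1 <= self.position <= len(self.sequence):
            raise ValueError(f"position {self.position} outside the sequence")
        if self.deviant_type == "sequence" and (
            self.deviant_item == self.sequence[self.position - 1]
        ):
            raise ValueError("a sequence deviant must differ from the original item")


def deviant_surprise(event: DeviantEvent, padding: float = DEFAULT_PADDING) -> float:
    """Surprise of the deviant given the ORIGINAL item at position - 1."""
    if event.position < 2:
        raise ValueError("surprise needs a predecessor (position >= 2)")
    model = estimate_transitions(event.sequence)
    prev = event.sequence[event.position - 2]
    return surprise(model, prev, event.deviant_item, padding)


def mean_deviant_surprise(
    seq: str,
    positions,
    padding: float = DEFAULT_PADDING,
    drop_zero_probability: bool = False,
) -> float:
    """Mean surprise over deviant positions, the deviant being the flip of
    the original item at each position.

    With ``drop_zero_probability`` the positions whose original transition
    probability to the deviant is exactly zero are excluded (the padding
    control analysis); if every position is dropped the mean is NaN.
    """
    validate_sequence(seq)
    model = estimate_transitions(seq)
    values = []
    for pos in positions:
        if not 2 <= pos <= len(seq):
            raise ValueError(f"deviant position {pos} out of range (needs 2..len)")
        prev = seq[pos - 2]
        deviant = flip(seq[pos - 1])
        if drop_zero_probability and model.conditional(prev, deviant) in (0.0, None):
            continue
        values.append(surprise(model, prev, deviant, padding))
    if not values:
        return math.nan
    return sum(values) / len(values)
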