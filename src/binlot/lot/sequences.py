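"""Binary sequences over the alphabet {A, B}: validation, canonical form,
catalogs and periodicity."""

from __future__ import annotations

from itertools import product

__all__ = ["validate_sequence", "flip", "canonicalize", "sequence_catalog", "period"]


def validate_sequence(seq: str) -> str:
    if not isinstance(seq, str) or not seq:
        raise ValueError("sequence must be a non-empty string over {A, B}")
    if any(c not in "AB" for c in seq):
        raise ValueError(f"sequence contains items outside {{A, B}}: {seq!r}")
    return seq


def flip(seq: str) -> str:
    """Swap the two item labels."""
    return seq.translate(str.maketrans("AB", "BA"))


def canonicalize(seq: str) -> str:
    """Representative of the relabeling class: flip all items if the first is B."""
    validate_sequence(seq)
    return flip(seq) if seq[0] == "B" else seq


def sequence_catalog(length: int, balanced_only: bool = False) -> list[str]:
    """All canonical sequences of a length, sorted lexicographically.

    The labeling of A and B being arbitrary, only sequences starting with A
    are listed (one per relabeling class).  With ``balanced_only`` the
    catalog is restricted to sequences with equal counts of A and B.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if length > 20:
        raise ValueError("catalog length capped at 20 (2^19 sequences already)")
    if balanced_only and length % 2:
        raise ValueError("balanced catalog requires an even length")
    out = []
    for tail in product("AB", repeat=length - 1):
        seq = "A" + "".join(tail)
        if balanced_only and 2 * seq.count("A") != length:
            continue
        out.append(seq)
    return out


def period(seq: str) -> int:
    """Smallest p dividing len(seq) with seq equal to its p-prefix repeated.

    Equals len(seq) for aperiodic sequences.
    """
    validate_sequence(seq)
    n = len(seq)
    for p in range(1, n):
        if n % p == 0 and seq == seq[:p] * (n // p):
            return p
    return n
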