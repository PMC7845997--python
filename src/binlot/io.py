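"""Readers and writers for sequence catalogs, trial tables and results.

CSV dialect: comma-separated, UTF-8, '.' decimal, mandatory header row.
Sequence catalogs are TSV with columns ``sequence_id`` and ``pattern``.
Patterns are stored canonicalized, with the original labeling kept in a
separate column.  Positions are 1-based throughout.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .behavior import TRIAL_COLUMNS
from .lot.sequences import canonicalize

__all__ = ["read_sequences", "read_trials", "write_tables", "MalformedInputError"]

logger = logging.getLogger(__name__)

REQUIRED_TRIAL_COLUMNS = [
    "participant",
    "sequence_id",
    "pattern",
    "deviant_type",
    "deviant_position",
    "rt_ms",
    "responded",
]

_TRIAL_DEFAULTS = {"experiment": "unknown", "modality": "auditory", "trial_index": 0}


class MalformedInputError(ValueError):
    """Unusable input file; the message carries file and line context."""


def read_sequences(path) -> pd.DataFrame:
    """Load a TSV catalog with columns ``sequence_id`` and ``pattern``.

    Rows whose pattern is not a string over {A, B} are rejected with their
    line numbers logged; an empty or header-less file raises.  Returns
    columns ``sequence_id``, ``pattern`` (canonical) and
    ``pattern_original``.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise MalformedInputError(f"{path}: empty catalog file") from None
    missing = {"sequence_id", "pattern"} - set(table.columns)
    if missing:
        raise MalformedInputError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            f"found {list(table.columns)}"
        )
    ok = table["pattern"].str.fullmatch("[AB]+").fillna(False)
    if not ok.all():
        for idx in table.index[~ok]:
            logger.warning(
                "%s: line %d: rejected pattern %r", path, idx + 2, table.loc[idx, "pattern"]
            )
        table = table[ok]
    if table.empty:
        raise MalformedInputError(f"{path}: no valid sequence rows")
    table = table.assign(
        pattern_original=table["pattern"],
        pattern=table["pattern"].map(canonicalize),
    )
    return table.reset_index(drop=True)


def read_trials(path, column_map: dict | None = None) -> pd.DataFrame:
    """Load a trial-level CSV into the internal trial schema.

    ``column_map`` renames external headers to the internal ones (e.g.
    ``{"subject": "participant"}``).  Header is validated; optional
    columns get neutral defaults; malformed patterns raise.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise MalformedInputError(f"{path}: empty trials file") from None
    if column_map:
        table = table.rename(columns=column_map)
    missing = set(REQUIRED_TRIAL_COLUMNS) - set(table.columns)
    if missing:
        raise MalformedInputError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            f"found {list(table.columns)}"
        )
    bad = ~table["pattern"].astype(str).str.fullmatch("[AB]+")
    if bad.any():
        lines = [int(i) + 2 for i in table.index[bad][:5]]
        raise MalformedInputError(
            f"{path}: {int(bad.sum())} row(s) with patterns outside {{A,B}} "
            f"(first at line(s) {lines})"
        )
    for col, default in _TRIAL_DEFAULTS.items():
        if col not in table.columns:
            table[col] = default
    table["responded"] = table["responded"].astype(bool)
    table["rt_ms"] = pd.to_numeric(table["rt_ms"], errors="coerce")
    table["deviant_position"] = pd.to_numeric(table["deviant_position"], errors="coerce")
    return table[TRIAL_COLUMNS]


def write_tables(results: dict, out_dir, config: dict | None = None) -> dict:
    """Write a dict of DataFrames as CSVs plus a provenance sidecar.

    ``provenance.json`` records the configuration passed in and a content
    hash of every written table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {"config": config or {}, "tables": {}}
    written = {}
    for name, table in results.items():
        target = out_dir / f"{name}.csv"
        table.to_csv(target, index=False)
        digest = hashlib.sha256(target.read_bytes()).hexdigest()[:16]
        provenance["tables"][name] = {"rows": len(table), "sha256_16": digest}
        written[name] = target
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    return written
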