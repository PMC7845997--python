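"""From trial tables to per-sequence performance scores.

The pipeline is deterministic: classify trials into hit / miss /
false-alarm / correct-rejection, trim extreme response times, compute the
linear integrated speed-accuracy score (LISAS) per participant x sequence
x deviant type, and flag participants with outlying overall performance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "HIT_WINDOW_MS",
    "LisasInputs",
    "classify_trials",
    "trim_rts",
    "lisas",
    "participant_lisas_scales",
    "exclude_participants",
    "sequence_scores",
]

logger = logging.getLogger(__name__)

HIT_WINDOW_MS = (200.0, 2500.0)

TRIAL_COLUMNS = [
    "participant",
    "experiment",
    "modality",
    "sequence_id",
    "pattern",
    "trial_index",
    "deviant_type",
    "deviant_position",
    "rt_ms",
    "responded",
]


@dataclass(frozen=True)
class LisasInputs:
    """Components of the LISAS formula for one scoring cell."""

    rt_c: float  # mean correct RT (ms)
    mr: float  # miss rate in [0, 1]
    s_rt: float  # participant's overall RT standard deviation (ms)
    s_mr: float  # participant's overall miss-indicator standard deviation


def lisas(inputs: LisasInputs) -> float:
    """rt_c + mr * (s_rt / s_mr); reduces to rt_c when nothing was missed."""
    if inputs.mr < 0 or inputs.mr > 1:
        raise ValueError("miss rate must lie in [0, 1]")
    if inputs.mr == 0:
        return inputs.rt_c
    if inputs.s_mr == 0:
        raise ValueError("s_mr is zero but the miss rate is positive")
    return inputs.rt_c + inputs.mr * (inputs.s_rt / inputs.s_mr)


def classify_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Append an ``outcome`` column; drop rows with negative RTs (logged).

    Deviant trials are hits iff a response fell inside the hit window
    (200-2500 ms after deviant onset), otherwise misses.  Non-deviant
    trials are false alarms iff any response occurred, else correct
    rejections.
    """
    trials = trials.copy()
    bad = trials["rt_ms"].notna() & (trials["rt_ms"] < 0)
    if bad.any():
        logger.warning("rejecting %d trial(s) with negative RT", int(bad.sum()))
        trials = trials[~bad].copy()
    lo, hi = HIT_WINDOW_MS
    is_deviant = trials["deviant_type"] != "none"
    in_window = trials["responded"] & trials["rt_ms"].between(lo, hi)
    outcome = np.where(
        is_deviant,
        np.where(in_window, "hit", "miss"),
        np.where(trials["responded"], "false_alarm", "correct_rejection"),
    )
    trials["outcome"] = outcome
    return trials


def trim_rts(
    trials: pd.DataFrame, multiplier: float = 2.5
) -> tuple[pd.DataFrame, float]:
    """Flag hit RTs further than ``multiplier`` cell-SDs from the cell median.

    A cell is (participant x sequence x deviant type).  Each RT is compared
    against the median and SD of the *other* RTs in its cell, so a single
    extreme value cannot mask itself by inflating the cell SD (with the
    plain cell SD no point can ever deviate by more than (n-1)/sqrt(n)
    SDs, making small cells untrimmable).  Trimming only removes trials
    from RT statistics (column ``rt_trimmed``); hit/miss tallies are
    unaffected.  Cells with fewer than 3 RTs, or zero leave-one-out SD,
    pass through untrimmed.  Returns the table and the removed fraction.
    """
    trials = trials.copy()
    trials["rt_trimmed"] = False
    hits = trials[trials["outcome"] == "hit"]
    for _, cell in hits.groupby(["participant", "sequence_id", "deviant_type"]):
        rts = cell["rt_ms"]
        if len(rts) < 3:
            continue
        for idx, value in rts.items():
            rest = rts.drop(idx)
            sd = rest.std(ddof=1)
            if sd == 0 or math.isnan(sd):
                continue
            if abs(value - rest.median()) > multiplier * sd:
                trials.loc[idx, "rt_trimmed"] = True
    n_hits = len(hits)
    fraction = float(trials["rt_trimmed"].sum()) / n_hits if n_hits else 0.0
    return trials, fraction


def participant_lisas_scales(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant overall s_rt and s_mr across all deviant trials.

    s_rt is the SD of the participant's untrimmed hit RTs; s_mr is the SD
    of the 0/1 miss indicator over all of the participant's deviant trials.
    """
    if "rt_trimmed" not in trials.columns:
        trials = trials.assign(rt_trimmed=False)
    deviants = trials[trials["deviant_type"] != "none"]
    rows = []
    for participant, grp in deviants.groupby("participant"):
        rt_ok = grp[(grp["outcome"] == "hit") & ~grp["rt_trimmed"]]
        s_rt = rt_ok["rt_ms"].std(ddof=1) if len(rt_ok) > 1 else np.nan
        miss = (grp["outcome"] == "miss").astype(float)
        s_mr = miss.std(ddof=1) if len(miss) > 1 else np.nan
        rows.append({"participant": participant, "s_rt": s_rt, "s_mr": s_mr})
    return pd.DataFrame(rows).set_index("participant")


def exclude_participants(
    summary: pd.DataFrame, multiplier: float = 2.5
) -> tuple[list, list]:
    """Split participants into (kept, excluded-with-reasons).

    ``summary`` is indexed by participant with columns among
    ``miss_rate``, ``mean_rt``, ``false_alarms``.  A participant is
    excluded when any of those quantities strictly exceeds the group
    median plus ``multiplier`` times the group SD around the median.
    """
    if len(summary) < 3:
        raise ValueError("participant exclusion needs at least 3 participants")
    reasons: dict = {}
    for col in ("miss_rate", "mean_rt", "false_alarms"):
        if col not in summary.columns:
            continue
        x = summary[col].astype(float)
        med = x.median()
        sd = math.sqrt(((x - med) ** 2).sum() / (len(x) - 1))
        threshold = med + multiplier * sd
        for participant in summary.index[x > threshold]:
            reasons.setdefault(participant, []).append(col)
    kept = [p for p in summary.index if p not in reasons]
    excluded = [(p, tuple(r)) for p, r in reasons.items()]
    if excluded:
        logger.info("excluding participants: %s", excluded)
    return kept, excluded


def sequence_scores(
    trials: pd.DataFrame,
    metrics: pd.DataFrame | None = None,
    surprise: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per (participant x sequence x deviant type) performance table.

    Expects classified (and normally trimmed) trials.  Emits one row per
    cell with mean correct RT, miss rate, LISAS, the per-sequence
    false-alarm count, and, when provided, the per-sequence predictor
    columns from ``metrics`` (joined on ``pattern``) and the per-cell mean
    deviant ``surprise`` (joined on pattern and deviant type).  Cells whose
    predictors are missing are flagged (``missing_predictors``), never
    dropped.
    """
    if "outcome" not in trials.columns:
        raise ValueError("trials must be classified first (no 'outcome' column)")
    if "rt_trimmed" not in trials.columns:
        trials = trials.assign(rt_trimmed=False)
    scales = participant_lisas_scales(trials)

    fa_counts = (
        trials[trials["outcome"] == "false_alarm"]
        .groupby(["participant", "sequence_id"])
        .size()
    )

    deviants = trials[trials["deviant_type"] != "none"]
    rows = []
    for (participant, seq_id, dtype), grp in deviants.groupby(
        ["participant", "sequence_id", "deviant_type"]
    ):
        pattern = grp["pattern"].iloc[0]
        hits = grp[grp["outcome"] == "hit"]
        rt_used = hits[~hits["rt_trimmed"]]["rt_ms"]
        rt_c = float(rt_used.mean()) if len(rt_used) else np.nan
        mr = float((grp["outcome"] == "miss").mean())
        s_rt = scales.loc[participant, "s_rt"]
        s_mr = scales.loc[participant, "s_mr"]
        if mr == 0:
            score = rt_c
        elif s_mr and not math.isnan(s_mr) and s_mr > 0:
            score = rt_c + mr * (s_rt / s_mr)
        else:
            score = np.nan
        rows.append(
            {
                "participant": participant,
                "experiment": grp["experiment"].iloc[0],
                "modality": grp["modality"].iloc[0],
                "sequence_id": seq_id,
                "pattern": pattern,
                "deviant_type": dtype,
                "n_trials": len(grp),
                "rt_c": rt_c,
                "miss_rate": mr,
                "lisas": score,
                "false_alarms": float(fa_counts.get((participant, seq_id), 0)),
            }
        )
    scores = pd.DataFrame(rows)
    if scores.empty:
        return scores

    # predictor columns that are empty in the *input* tables (e.g. no
    # lookup table was provided at all) are not counted as "missing"
    predictor_cols: list[str] = []
    if metrics is not None:
        predictor_cols += [
            c for c in metrics.columns if c != "pattern" and metrics[c].notna().any()
        ]
        scores = scores.merge(metrics, on="pattern", how="left", validate="m:1")
    if surprise is not None:
        keys = [c for c in ("pattern", "deviant_type") if c in surprise.columns]
        predictor_cols += [
            c for c in surprise.columns if c not in keys and surprise[c].notna().any()
        ]
        scores = scores.merge(surprise, on=keys, how="left")
    if metrics is not None or surprise is not None:
        missing = (
            scores[predictor_cols].isna().any(axis=1)
            if predictor_cols
            else pd.Series(False, index=scores.index)
        )
        scores["missing_predictors"] = missing
        if missing.any():
            logger.warning(
                "%d score row(s) have missing predictor values", int(missing.sum())
            )
    return scores
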