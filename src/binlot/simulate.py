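"""Synthetic deviant-detection trial tables with known ground truth.

Response times depend linearly, and miss probabilities logistically, on
sequence complexity and deviant surprise, with participant-level random
intercepts -- exactly the structure assumed by the analysis pipeline, so
simulated tables support end-to-end and parameter-recovery tests without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import TRIAL_COLUMNS
from .lot.search import minimal_description
from .lot.sequences import flip, validate_sequence
from .surprise import DEFAULT_PADDING, estimate_transitions, surprise

__all__ = ["RtModel", "MissModel", "SimConfig", "simulate_trials", "make_experiment_designs"]


@dataclass(frozen=True)
class RtModel:
    """Linear RT model (ms): beta0 + b_complexity*C + b_surprise*S + u_p + eps."""

    beta0: float = 645.0
    beta_complexity: float = 30.0
    beta_surprise: float = -20.0
    participant_sd: float = 80.0
    residual_sd: float = 150.0
    lognormal: bool = False  # draw eps on the log scale instead (heavier tail)


@dataclass(frozen=True)
class MissModel:
    """Log-odds of missing a deviant: gamma0 + g_complexity*C + g_surprise*S."""

    gamma0: float = -3.0
    gamma_complexity: float = 0.15
    gamma_surprise: float = -0.1


@dataclass(frozen=True)
class SimConfig:
    name: str
    sequences: tuple
    deviant_positions: dict  # pattern -> tuple of 1-based positions
    n_participants: int = 20
    trials_per_cell: int = 12  # deviant trials per participant x sequence
    standard_trials: int = 24  # per participant x sequence block
    rt_model: RtModel = field(default_factory=RtModel)
    miss_model: MissModel = field(default_factory=MissModel)
    fa_rate: float = 1.0  # Poisson mean false alarms per standard block
    modality: str = "auditory"
    padding: float = DEFAULT_PADDING
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        if not self.sequences or self.n_participants < 1 or self.trials_per_cell < 1:
            raise ValueError("config needs sequences, participants and trials")
        for pattern in self.sequences:
            validate_sequence(pattern)
            positions = self.deviant_positions.get(pattern)
            if not positions:
                raise ValueError(f"no deviant positions for {pattern!r}")
            if any(not 2 <= p <= len(pattern) for p in positions):
                raise ValueError(f"deviant positions out of range for {pattern!r}")
        if self.rt_model.participant_sd <= 0 or self.rt_model.residual_sd <= 0:
            raise ValueError("RT standard deviations must be positive")


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_trials(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Generate one trial table plus its ground-truth bundle.

    Deviant trials cycle deterministically through the configured
    positions; RTs are truncated below at 200 ms; false alarms are drawn
    per standard block from a Poisson and assigned to standard trials.
    The same seed always yields an identical table.
    """
    rng = np.random.default_rng(config.seed)
    rt_m, miss_m = config.rt_model, config.miss_model

    complexity = {p: minimal_description(p).complexity for p in config.sequences}
    surprise_at: dict = {}
    for pattern in config.sequences:
        model = estimate_transitions(pattern)
        for pos in config.deviant_positions[pattern]:
            prev = pattern[pos - 2]
            deviant = flip(pattern[pos - 1])
            surprise_at[pattern, pos] = surprise(model, prev, deviant, config.padding)

    intercepts = rng.normal(0.0, rt_m.participant_sd, size=config.n_participants)
    rows = []
    expectations = {}
    for pi in range(config.n_participants):
        participant = f"p{pi + 1:03d}"
        for si, pattern in enumerate(config.sequences):
            seq_id = f"s{si + 1:03d}"
            positions = config.deviant_positions[pattern]
            trial = 0
            for k in range(config.trials_per_cell):
                pos = positions[k % len(positions)]
                C, S = complexity[pattern], surprise_at[pattern, pos]
                mu = rt_m.beta0 + rt_m.beta_complexity * C + rt_m.beta_surprise * S
                if rt_m.lognormal:
                    noise = rt_m.residual_sd * (rng.lognormal(0.0, 0.5) - np.exp(0.125))
                else:
                    noise = rng.normal(0.0, rt_m.residual_sd)
                rt = max(200.0, mu + intercepts[pi] + noise)
                p_miss = _logistic(
                    miss_m.gamma0 + miss_m.gamma_complexity * C + miss_m.gamma_surprise * S
                )
                missed = rng.random() < p_miss
                trial += 1
                rows.append(
                    {
                        "participant": participant,
                        "experiment": config.name,
                        "modality": config.modality,
                        "sequence_id": seq_id,
                        "pattern": pattern,
                        "trial_index": trial,
                        "deviant_type": "sequence",
                        "deviant_position": pos,
                        "rt_ms": np.nan if missed else round(rt, 3),
                        "responded": not missed,
                    }
                )
                expectations.setdefault((pattern, pos), {
                    "mean_rt": mu, "p_miss": p_miss, "complexity": C, "surprise": S,
                })
            n_fa = min(int(rng.poisson(config.fa_rate)), config.standard_trials)
            fa_slots = set(rng.choice(config.standard_trials, size=n_fa, replace=False))
            for k in range(config.standard_trials):
                trial += 1
                responded = k in fa_slots
                rows.append(
                    {
                        "participant": participant,
                        "experiment": config.name,
                        "modality": config.modality,
                        "sequence_id": seq_id,
                        "pattern": pattern,
                        "trial_index": trial,
                        "deviant_type": "none",
                        "deviant_position": pd.NA,
                        "rt_ms": round(float(rng.uniform(300, 2000)), 3) if responded else np.nan,
                        "responded": responded,
                    }
                )
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    truth = {
        "config": config,
        "participant_intercepts": dict(
            zip((f"p{i + 1:03d}" for i in range(config.n_participants)), intercepts)
        ),
        "complexity": complexity,
        "surprise": {f"{p}@{pos}": s for (p, pos), s in surprise_at.items()},
        "cell_expectations": {
            f"{p}@{pos}": v for (p, pos), v in expectations.items()
        },
    }
    return trials, truth


def _second_half_positions(pattern: str, count: int = 4) -> tuple:
    n = len(pattern)
    positions = list(range(n // 2 + 1, n + 1))
    return tuple(positions[-count:]) if len(positions) > count else tuple(positions)


def make_experiment_designs(seed: int = 0) -> dict:
    """Preset configurations echoing the five deviant-detection designs.

    Lengths 16 / 12 / 8 / 6 / 8.  The length-8 and length-6 presets use
    the full canonical catalogs (35 balanced and 32 sequences).  The
    length-16 and length-12 presets include the sequences named in the
    running text plus deterministic catalog stand-ins (the original full
    lists only exist in figures), flagged in the config name.
    """
    from .lot.sequences import sequence_catalog

    rng = np.random.default_rng(seed)

    exp1_named = [
        "ABABABABABABABAB",
        "AABBAABBAABBAABB",
        "AAAABBBBAAAABBBB",
        "AAAAAAAABBBBBBBB",
        "AABBABABAABBABAB",
        "ABAAABABAABBBABB",
    ]
    pool16 = [
        s for s in sequence_catalog(16, balanced_only=True) if s not in exp1_named
    ]
    exp1 = exp1_named + [pool16[int(i)] for i in rng.choice(len(pool16), 4, replace=False)]

    exp2_named = ["ABBAABABBAAB", "AAAAAABBBBBB", "ABABABABABAB"]
    pool12 = [s for s in sequence_catalog(12, balanced_only=True) if s not in exp2_named]
    exp2 = exp2_named + [pool12[int(i)] for i in rng.choice(len(pool12), 9, replace=False)]

    exp3 = sequence_catalog(8, balanced_only=True)
    exp4 = sequence_catalog(6)
    exp5 = exp3[:: len(exp3) // 15][:15]

    def cfg(name, seqs, positions, **kw):
        return SimConfig(
            name=name,
            sequences=tuple(seqs),
            deviant_positions={s: positions for s in seqs},
            seed=seed,
            **kw,
        )

    designs = {
        "exp1": cfg("exp1-len16-standins", exp1, (9, 11, 13, 15),
                    rt_model=RtModel(beta0=357.0, beta_complexity=52.0)),
        "exp2": cfg("exp2-len12-standins", exp2, (7, 8, 9, 10, 11, 12),
                    rt_model=RtModel(beta0=852.0, beta_complexity=30.0)),
        "exp3": cfg("exp3-len8-catalog", exp3, (5, 6, 7, 8),
                    rt_model=RtModel(beta0=751.0, beta_complexity=25.0)),
        "exp4": cfg("exp4-len6-catalog", exp4, (4, 5, 6),
                    rt_model=RtModel(beta0=645.0, beta_complexity=1.4, beta_surprise=-43.0)),
        "exp5": cfg("exp5-len8-bimodal", exp5, (5, 6, 7, 8),
                    rt_model=RtModel(beta0=780.0, beta_complexity=22.0)),
    }
    return designs
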