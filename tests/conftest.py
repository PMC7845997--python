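import numpy as np
import pandas as pd
import pytest

from binlot import behavior
from binlot.metrics import metrics_table
from binlot.simulate import MissModel, RtModel, SimConfig, simulate_trials
from binlot.surprise import mean_deviant_surprise


def mean_surprise_table(trials: pd.DataFrame, padding: float = 0.01) -> pd.DataFrame:
    rows = []
    deviants = trials[trials["deviant_type"] == "sequence"]
    for pattern, grp in deviants.groupby("pattern"):
        positions = sorted(grp["deviant_position"].dropna().astype(int).unique())
        rows.append(
            {
                "pattern": pattern,
                "deviant_type": "sequence",
                "surprise": mean_deviant_surprise(pattern, positions, padding),
            }
        )
    return pd.DataFrame(rows)


def small_config(seed: int = 0, **overrides) -> SimConfig:
    sequences = ("AAAABBBB", "ABABABAB", "AABBABBA", "AAABABBB", "ABBABBBA")
    defaults = dict(
        name="toy",
        sequences=sequences,
        deviant_positions={s: (5, 6, 7, 8) for s in sequences},
        n_participants=8,
        trials_per_cell=8,
        standard_trials=8,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def simulate_scores(config: SimConfig) -> pd.DataFrame:
    """Full simulate -> classify -> trim -> score pipeline."""
    trials, _ = simulate_trials(config)
    trials = behavior.classify_trials(trials)
    trials, _ = behavior.trim_rts(trials)
    metrics = metrics_table(sorted(set(config.sequences)))
    surprise = mean_surprise_table(trials, config.padding)
    return behavior.sequence_scores(trials, metrics=metrics, surprise=surprise)


@pytest.fixture(scope="session")
def toy_scores() -> pd.DataFrame:
    return simulate_scores(small_config(seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
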