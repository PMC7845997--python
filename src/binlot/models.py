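"""Random-intercept mixed models, likelihood-ratio tests and the
AIC/BIC/Akaike-weight model race.

All models are fitted by maximum likelihood (never REML) so that
log-likelihoods, AICs and likelihood-ratio tests are comparable across
fixed-effect structures.  The parameter count entering AIC/BIC is the
number of fixed effects (incl. intercept) plus the two variance
components (random-intercept and residual variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "FitResult",
    "fit_lmm",
    "likelihood_ratio_test",
    "akaike_weights",
    "model_race",
    "per_sequence_correlation",
    "compare_predictor_correlations",
]


@dataclass(frozen=True)
class ModelSpec:
    """Response ~ fixed effects with a per-group random intercept."""

    response: str
    fixed: tuple
    grouping: str = "participant"

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", tuple(self.fixed))

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        return f"{self.response} ~ {rhs}"


@dataclass(frozen=True)
class FitResult:
    """Summary of one maximum-likelihood fit."""

    spec: ModelSpec
    log_lik: float
    n_params: int
    n_obs: int
    coefficients: dict  # name -> (estimate, std_error, t)
    variance_components: tuple  # (random-intercept variance, residual variance)
    converged: bool = True
    degraded_to_ols: bool = False

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.log_lik

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_obs) - 2 * self.log_lik


def _complete_cases(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    cols = [spec.response, *spec.fixed, spec.grouping]
    sub = data[cols].dropna()
    if sub.empty:
        raise ValueError("no complete-case rows for this model")
    return sub


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """ML fit of a random-intercept linear mixed model.

    If the mixed-model optimizer fails outright, the fit degrades to
    ordinary least squares (zero group variance) with a flag rather than
    raising; with truly zero between-group variance the two coincide.
    """
    sub = _complete_cases(data, spec)
    if sub[spec.grouping].nunique() < 2:
        raise ValueError("grouping factor needs at least 2 levels")
    n_fixed = len(spec.fixed) + 1  # + intercept
    n_params = n_fixed + 2
    fit = None
    for method in ("bfgs", "lbfgs", "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(spec.formula, sub, groups=sub[spec.grouping])
                candidate = model.fit(reml=False, method=method, maxiter=2000)
            if np.isfinite(candidate.llf):
                fit = candidate
                break
        except Exception:
            continue
    if fit is not None:
        coefficients = {}
        for name in fit.fe_params.index:
            est = float(fit.fe_params[name])
            se = float(fit.bse_fe[name])
            coefficients[name] = (est, se, est / se if se > 0 else np.nan)
        group_var = float(fit.cov_re.iloc[0, 0])
        resid_var = float(fit.scale)
        return FitResult(
            spec=spec,
            log_lik=float(fit.llf),
            n_params=n_params,
            n_obs=len(sub),
            coefficients=coefficients,
            variance_components=(group_var, resid_var),
            converged=bool(fit.converged),
        )
    else:  # singular / failed optimization: fall back to OLS
        fit = smf.ols(spec.formula, sub).fit()
        coefficients = {
            name: (float(fit.params[name]), float(fit.bse[name]), float(fit.tvalues[name]))
            for name in fit.params.index
        }
        resid_var = float(fit.ssr / len(sub))  # ML residual variance
        return FitResult(
            spec=spec,
            log_lik=float(fit.llf),
            n_params=n_params,
            n_obs=len(sub),
            coefficients=coefficients,
            variance_components=(0.0, resid_var),
            converged=True,
            degraded_to_ols=True,
        )


def likelihood_ratio_test(null: FitResult, full: FitResult) -> tuple[float, int, float]:
    """(chi2, df, p) for nested ML fits; ``null`` must nest in ``full``."""
    if not set(null.spec.fixed) <= set(full.spec.fixed):
        raise ValueError("null model fixed effects are not a subset of the full model's")
    if null.spec.response != full.spec.response or null.spec.grouping != full.spec.grouping:
        raise ValueError("models must share response and grouping")
    df = full.n_params - null.n_params
    chi2 = 2.0 * (full.log_lik - null.log_lik)
    if df == 0:
        return chi2, 0, 1.0
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return chi2, df, p


def akaike_weights(aic_values: Sequence[float]) -> np.ndarray:
    """exp(-delta_i / 2) normalized over the model set."""
    aic = np.asarray(aic_values, dtype=float)
    if aic.size < 2:
        raise ValueError("need at least two AIC values")
    if not np.all(np.isfinite(aic)):
        raise ValueError("AIC values must be finite")
    delta = aic - aic.min()
    raw = np.exp(-delta / 2.0)
    return raw / raw.sum()


def model_race(
    scores: pd.DataFrame,
    predictors: Sequence[str],
    with_and_without_surprise: bool = True,
    surprise_col: str = "surprise",
    response: str = "lisas",
    grouping: str = "participant",
) -> pd.DataFrame:
    """Race single-predictor random-intercept models, with and without the
    surprise covariate.

    Rows with a missing value in any raced column are dropped listwise so
    every model sees the same data.  Each model's row reports log_lik,
    aic, bic, the deltas to the per-race minima, and the Akaike weight
    over the converged models; a model whose fit fails is flagged
    (``failed``) and excluded from the weights without aborting the race.
    """
    predictors = list(predictors)
    cols = {response, grouping, *predictors}
    if with_and_without_surprise:
        cols.add(surprise_col)
    data = scores.dropna(subset=[c for c in cols if c in scores.columns])
    specs = []
    for pred in predictors:
        specs.append((pred, False, ModelSpec(response, (pred,), grouping)))
        if with_and_without_surprise:
            specs.append((pred, True, ModelSpec(response, (pred, surprise_col), grouping)))
    rows = []
    for pred, with_surprise, spec in specs:
        row = {"predictor": pred, "with_surprise": with_surprise}
        try:
            fit = fit_lmm(data, spec)
            row.update(
                log_lik=fit.log_lik,
                aic=fit.aic,
                bic=fit.bic,
                n_params=fit.n_params,
                n_obs=fit.n_obs,
                failed=False,
            )
        except Exception as exc:
            row.update(log_lik=np.nan, aic=np.nan, bic=np.nan, failed=True, error=str(exc))
        rows.append(row)
    race = pd.DataFrame(rows)
    ok = ~race["failed"]
    if ok.any():
        race.loc[ok, "delta_aic"] = race.loc[ok, "aic"] - race.loc[ok, "aic"].min()
        race.loc[ok, "delta_bic"] = race.loc[ok, "bic"] - race.loc[ok, "bic"].min()
        if ok.sum() >= 2:
            race.loc[ok, "w_aic"] = akaike_weights(race.loc[ok, "aic"].to_numpy())
    return race.sort_values("aic").reset_index(drop=True)


def per_sequence_correlation(
    scores: pd.DataFrame,
    predictor: str,
    response: str = "lisas",
    grouping: str = "participant",
    pattern_col: str = "pattern",
) -> tuple[float, pd.Series]:
    """Pearson r between a predictor and the participant-averaged response
    per sequence, plus the within-participant r distribution."""
    sub = scores.dropna(subset=[predictor, response])
    per_seq = sub.groupby(pattern_col)[[predictor, response]].mean()
    if len(per_seq) < 3:
        raise ValueError("need at least 3 sequences")
    if per_seq[predictor].nunique() < 2:
        raise ValueError(f"predictor {predictor!r} has no variance across sequences")
    r = float(stats.pearsonr(per_seq[predictor], per_seq[response])[0])

    def _r(grp: pd.DataFrame) -> float:
        if len(grp) < 3 or grp[predictor].nunique() < 2 or grp[response].nunique() < 2:
            return np.nan
        return float(stats.pearsonr(grp[predictor], grp[response])[0])

    per_participant = sub.groupby(grouping).apply(_r, include_groups=False)
    return r, per_participant


def compare_predictor_correlations(
    scores: pd.DataFrame,
    predictor_a: str,
    predictor_b: str,
    response: str = "lisas",
    grouping: str = "participant",
) -> tuple[float, float]:
    """Paired t-test between two predictors' within-participant r values."""
    _, ra = per_sequence_correlation(scores, predictor_a, response, grouping)
    _, rb = per_sequence_correlation(scores, predictor_b, response, grouping)
    paired = pd.concat([ra, rb], axis=1, keys=["a", "b"]).dropna()
    t, p = stats.ttest_rel(paired["a"], paired["b"])
    return float(t), float(p)
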