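"""Cox proportional-hazards comparison of volume vs thickness-shape models.

Two nested-adjustment Cox models are fit per disease outcome (and per
stratum, typically sex): a *volume model* with total tissue volume plus
the anthropometric adjustment set, and a *thickness model* in which the
volume term is replaced by the leading sparse-PCA scores of the vertex
thickness field. Models are compared by AIC (partial likelihood) and
Harrell's concordance index; hazard-ratio p values are BH-FDR adjusted
per model. Efron tie handling, Wald confidence intervals; continuous
covariates are z-scored before fitting so hazard ratios read per SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurvivalTable",
    "CoxFit",
    "fit_cox",
    "compare_models",
    "run_survival_study",
]

#: Covariates that may not enter the thickness model (collinear with the
#: shape scores by construction).
THICKNESS_MODEL_EXCLUDED = ("total_muscle_l",)


@dataclass
class SurvivalTable:
    """Time-to-event table with covariates.

    Times are positive (subjects with an event before baseline are
    excluded upstream); the event flag is 0/1.
    """

    data: pd.DataFrame
    duration_col: str = "time"
    event_col: str = "event"

    def __post_init__(self) -> None:
        df = self.data
        for col in (self.duration_col, self.event_col):
            if col not in df.columns:
                raise ValueError(f"missing column {col!r}")
        if (df[self.duration_col] <= 0).any():
            raise ValueError("all times must be positive")
        if not set(df[self.event_col].unique()) <= {0, 1}:
            raise ValueError("event flag must be 0/1")
        if df.isna().any().any():
            raise ValueError("survival table contains missing values (complete-case analysis only)")


@dataclass
class CoxFit:
    """Summaries of one proportional-hazards fit."""

    coefficients: pd.Series
    covariance: pd.DataFrame
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p_values: pd.Series
    q_values: pd.Series
    log_partial_likelihood: float
    aic: float
    concordance: float
    n: int
    n_events: int
    subject_index: pd.Index

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "HR_lower95": self.ci_lower,
                "HR_upper95": self.ci_upper,
                "p": self.p_values,
                "q_fdr": self.q_values,
            }
        )


def _standardize_continuous(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    out = df.copy()
    for col in covariates:
        v = out[col].to_numpy(float)
        uniq = np.unique(v)
        if len(uniq) <= 2:  # binary indicator: leave on its category scale
            continue
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"constant covariate: {col!r}")
        out[col] = (v - v.mean()) / sd
    return out


def fit_cox(
    table: SurvivalTable,
    covariates: list[str],
    fdr_q: float = 0.05,
    standardize: bool = True,
) -> CoxFit:
    """Fit a Cox model (Efron ties) and package HRs, CIs, AIC, c-index.

    Continuous covariates are z-scored when ``standardize`` is set; binary
    columns stay on their category scale. Raises on zero events, constant
    covariates, or separation (non-convergence).
    """
    df = table.data
    n_events = int(df[table.event_col].sum())
    if n_events == 0:
        raise ValueError("no events in the survival table")
    for col in covariates:
        if df[col].nunique() <= 1:
            raise ValueError(f"constant covariate: {col!r}")
    sub = df[[table.duration_col, table.event_col] + list(covariates)]
    if standardize:
        sub = _standardize_continuous(sub, list(covariates))
    cph = CoxPHFitter()
    try:
        cph.fit(sub, duration_col=table.duration_col, event_col=table.event_col)
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox model failed to converge (possible separation): {exc}") from exc
    summ = cph.summary
    p = summ["p"]
    _, q, *_ = multipletests(p.to_numpy(), alpha=fdr_q, method="fdr_bh")
    return CoxFit(
        coefficients=cph.params_,
        covariance=cph.variance_matrix_,
        hazard_ratios=np.exp(cph.params_),
        ci_lower=np.exp(summ["coef lower 95%"]),
        ci_upper=np.exp(summ["coef upper 95%"]),
        p_values=p,
        q_values=pd.Series(q, index=p.index),
        log_partial_likelihood=float(cph.log_likelihood_),
        aic=float(cph.AIC_partial_),
        concordance=float(cph.concordance_index_),
        n=len(sub),
        n_events=n_events,
        subject_index=df.index,
    )


def compare_models(fit_volume: CoxFit, fit_thickness: CoxFit) -> dict:
    """AIC and c-index comparison of two fits on the same subjects.

    AIC = 2k - 2 logPL (lower is better); c-index is Harrell's
    concordance over usable pairs (higher is better).
    """
    if not fit_volume.subject_index.equals(fit_thickness.subject_index):
        raise ValueError("model comparison requires identical subject sets")
    report = {
        "aic_volume": fit_volume.aic,
        "aic_thickness": fit_thickness.aic,
        "aic_winner": "thickness" if fit_thickness.aic < fit_volume.aic else "volume",
        "cindex_volume": fit_volume.concordance,
        "cindex_thickness": fit_thickness.concordance,
        "cindex_winner": "thickness"
        if fit_thickness.concordance > fit_volume.concordance
        else "volume",
        "n": fit_volume.n,
        "n_events": fit_volume.n_events,
    }
    return report


def run_survival_study(
    covariate_table: pd.DataFrame,
    survival_table: SurvivalTable,
    pc_scores: pd.DataFrame,
    adjustment: list[str],
    volume_col: str = "asat_volume_l",
    n_pcs: int = 4,
    fdr_q: float = 0.05,
    min_events_per_covariate: int = 10,
) -> dict:
    """Fit and compare the volume and thickness-PC Cox models.

    The volume model uses ``adjustment + [volume_col]``; the thickness
    model replaces the volume term with the first ``n_pcs`` standardized
    PC-score columns of ``pc_scores`` (named ``PC1..PCk``). Covariates in
    :data:`THICKNESS_MODEL_EXCLUDED` are rejected from the thickness
    adjustment set (collinear with the shape scores). Fewer than
    ``min_events_per_covariate`` events per covariate logs a warning but
    does not abort.
    """
    import logging

    log = logging.getLogger(__name__)
    excluded = [c for c in adjustment if c in THICKNESS_MODEL_EXCLUDED]
    if excluded:
        raise ValueError(
            f"covariates {excluded} may not enter the thickness model (correlated with PCs); "
            "drop them from the adjustment set"
        )
    if n_pcs > pc_scores.shape[1]:
        raise ValueError(f"requested {n_pcs} PCs, scores table has {pc_scores.shape[1]}")
    df = covariate_table.copy()
    base = survival_table.data
    if len(df) != len(base):
        raise ValueError("covariate table and survival table must cover the same subjects")
    pc_cols = list(pc_scores.columns[:n_pcs])
    merged = pd.concat(
        [base[[survival_table.duration_col, survival_table.event_col]], df, pc_scores[pc_cols]],
        axis=1,
    )

    n_events = int(base[survival_table.event_col].sum())
    n_covs = max(len(adjustment) + 1, len(adjustment) + n_pcs)
    if n_events < min_events_per_covariate * n_covs:
        log.warning(
            "only %d events for %d covariates (< %d per covariate); estimates may be unstable",
            n_events,
            n_covs,
            min_events_per_covariate,
        )

    table = SurvivalTable(merged, survival_table.duration_col, survival_table.event_col)
    fit_volume = fit_cox(table, adjustment + [volume_col], fdr_q=fdr_q)
    fit_thickness = fit_cox(table, adjustment + pc_cols, fdr_q=fdr_q)
    return {
        "volume": fit_volume,
        "thickness": fit_thickness,
        "comparison": compare_models(fit_volume, fit_thickness),
    }
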