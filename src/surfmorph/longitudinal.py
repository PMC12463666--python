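"""Per-vertex random-intercept linear mixed models for two-visit change.

Thickness at each template vertex is modelled on the stacked
subject-visit observations as

    y_iv = x_iv' beta + b_i + eps_iv,   b_i ~ N(0, sigma_b^2),  eps ~ N(0, sigma^2),

with subject as the random effect and fixed effects for visit, disease,
their interaction and the adjustment covariates. Fitting is REML by 1-D
profile optimisation over the variance ratio rho = sigma_b^2 / sigma^2:
for a given rho the marginal covariance is block-diagonal with
per-subject blocks ``I + rho * 1 1'``, whose inverse is analytic
(Woodbury), so each profile evaluation is a GLS fit. Wald p values use
the normal reference; at cohort sizes in the thousands the difference
from a t-approximation is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .spm import bh_fdr
from .thickness import CohortMatrix

__all__ = [
    "LongitudinalTable",
    "LMMResult",
    "fit_vertex_lmm",
    "run_longitudinal_map",
]

RHO_MAX = 1e4  # upper bound of the profiled variance ratio


@dataclass
class LongitudinalTable:
    """Stacked subject-visit observations.

    ``data`` rows carry subject id, visit (0 baseline / 1 follow-up),
    the disease indicator and covariates; each subject appears once or
    twice.
    """

    data: pd.DataFrame
    subject_col: str = "subject"
    visit_col: str = "visit"

    def __post_init__(self) -> None:
        df = self.data
        for col in (self.subject_col, self.visit_col):
            if col not in df.columns:
                raise ValueError(f"missing column {col!r}")
        visits = set(df[self.visit_col].unique())
        if not visits <= {0, 1}:
            raise ValueError("visit must be coded 0 (baseline) / 1 (follow-up)")
        counts = df.groupby(self.subject_col).size()
        if counts.max() > 2:
            raise ValueError("each subject may have at most 2 rows")

    @property
    def n_paired(self) -> int:
        counts = self.data.groupby(self.subject_col).size()
        return int((counts == 2).sum())


@dataclass
class LMMResult:
    """Per-vertex fixed effects, variance components and FDR masks."""

    effects: list[str]
    beta: dict = field(default_factory=dict)  # effect -> (V,)
    se: dict = field(default_factory=dict)
    p: dict = field(default_factory=dict)
    sig: dict = field(default_factory=dict)
    sigma2_b: np.ndarray | None = None
    sigma2_e: np.ndarray | None = None
    visit_summary: dict | None = None


def _column(df: pd.DataFrame, name: str) -> np.ndarray:
    """Resolve a fixed-effect name; ``a:b`` denotes the interaction a*b."""
    if ":" in name:
        parts = name.split(":")
        out = np.ones(len(df))
        for p in parts:
            out = out * df[p].to_numpy(float)
        return out
    return df[name].to_numpy(float)


def _group_structures(subject_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (group index per row, group sizes) for contiguous coding."""
    _, groups = np.unique(subject_codes, return_inverse=True)
    sizes = np.bincount(groups)
    return groups, sizes


def _gls_pieces(X: np.ndarray, Y: np.ndarray, groups: np.ndarray, sizes: np.ndarray, rho: float):
    """X'V*inv X, X'V*inv Y, Y'V*inv Y and log|V*| for V* = I + rho*ZZ'.

    ``Y`` may hold many vertices as columns; all contractions use the
    Woodbury identity through per-subject sums.
    """
    n_i = sizes[groups].astype(float)
    shrink = rho / (1.0 + rho * n_i)  # per-row coefficient of its group's sum
    # group sums
    GX = np.zeros((len(sizes), X.shape[1]))
    np.add.at(GX, groups, X)
    GY = np.zeros((len(sizes), Y.shape[1]))
    np.add.at(GY, groups, Y)
    Xa = X - shrink[:, None] * GX[groups]
    # V*inv x = x - shrink * groupsum(x); contractions:
    XtVX = X.T @ Xa
    XtVY = Xa.T @ Y
    g_shrink = rho / (1.0 + rho * sizes.astype(float))
    YtVY = np.einsum("ij,ij->j", Y, Y) - np.einsum("i,ij->j", g_shrink, GY**2)
    logdet = float(np.log1p(rho * sizes).sum())
    return XtVX, XtVY, YtVY, logdet


def _reml_neg2(rho: float, X: np.ndarray, y: np.ndarray, groups: np.ndarray, sizes: np.ndarray) -> float:
    """-2 * restricted log-likelihood profile in rho (up to a constant)."""
    n, p = X.shape
    XtVX, XtVy, ytVy, logdet = _gls_pieces(X, y[:, None], groups, sizes, rho)
    sign, logdet_X = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtVX, XtVy[:, 0])
    rss = float(ytVy[0] - beta @ XtVy[:, 0])
    if rss <= 0:
        rss = np.finfo(float).tiny
    return logdet + logdet_X + (n - p) * np.log(rss)


def fit_vertex_lmm(
    table: LongitudinalTable,
    y: np.ndarray,
    fixed_effects: list[str],
    rho_grid: np.ndarray | None = None,
) -> dict:
    """REML random-intercept fit for one vertex.

    ``fixed_effects`` are column names of ``table.data`` (an intercept is
    always included). Returns betas, SEs, normal-reference Wald p values
    and the variance components.
    """
    df = table.data
    groups, sizes = _group_structures(df[table.subject_col].to_numpy())
    if (sizes >= 2).sum() < 2:
        raise ValueError(
            "random-intercept variance is unidentifiable: need >= 2 subjects with repeated visits"
        )
    X = np.column_stack([np.ones(len(df))] + [_column(df, c) for c in fixed_effects])
    names = ["intercept"] + list(fixed_effects)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    y = np.asarray(y, dtype=float)

    obj = lambda r: _reml_neg2(r, X, y, groups, sizes)
    if rho_grid is None:
        rho_grid = np.concatenate([[0.0], np.geomspace(1e-4, RHO_MAX, 60)])
    vals = np.array([obj(r) for r in rho_grid])
    i = int(np.argmin(vals))
    lo = rho_grid[max(i - 1, 0)]
    hi = rho_grid[min(i + 1, len(rho_grid) - 1)]
    if hi > lo:
        res = minimize_scalar(obj, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8})
        rho = float(res.x) if res.fun <= vals[i] else float(rho_grid[i])
    else:
        rho = float(rho_grid[i])

    n, p = X.shape
    XtVX, XtVy, ytVy, _ = _gls_pieces(X, y[:, None], groups, sizes, rho)
    XtVX_inv = np.linalg.inv(XtVX)
    beta = XtVX_inv @ XtVy[:, 0]
    rss = float(ytVy[0] - beta @ XtVy[:, 0])
    sigma2 = rss / (n - p)
    se = np.sqrt(np.diag(XtVX_inv) * sigma2)
    from scipy.stats import norm

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    pvals = 2 * norm.sf(np.abs(z))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return {
        "effects": names,
        "beta": dict(zip(names, beta)),
        "se": dict(zip(names, se)),
        "p": dict(zip(names, pvals)),
        "rho": rho,
        "sigma2_e": sigma2,
        "sigma2_b": rho * sigma2,
    }


def run_longitudinal_map(
    table: LongitudinalTable,
    visit1: CohortMatrix,
    visit2: CohortMatrix,
    fixed_effects: list[str],
    fdr_q: float = 0.05,
    standardize_continuous: list[str] | None = None,
) -> LMMResult:
    """Fit the random-intercept model at every template vertex.

    ``visit1``/``visit2`` hold the baseline and follow-up thickness
    matrices for the same subjects; ``table`` carries one row per
    subject-visit observation, in any order — rows are matched to matrix
    rows through the matrices' subject ids. Continuous fixed effects
    named in ``standardize_continuous`` are z-scored. Each effect map is
    BH-FDR thresholded over vertices, and the visit effect is additionally
    summarised as the median change (response units) over significant
    vertices, split by sign.
    """
    if visit1.n_vertices != visit2.n_vertices:
        raise ValueError("visit matrices must share the template vertex count")
    if visit1.n_subjects != visit2.n_subjects:
        raise ValueError("visit matrices must cover the same subjects")
    df = table.data.copy()
    if len(df) != visit1.n_subjects + visit2.n_subjects:
        raise ValueError("table rows must match stacked visit matrices")
    if standardize_continuous:
        for col in standardize_continuous:
            v = df[col].to_numpy(float)
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError(f"zero-variance continuous fixed effect: {col!r}")
            df[col] = (v - v.mean()) / sd
    table_s = LongitudinalTable(df, table.subject_col, table.visit_col)
    lookup = {
        0: {sid: i for i, sid in enumerate(visit1.subject_ids)},
        1: {sid: i for i, sid in enumerate(visit2.subject_ids)},
    }
    matrices = {0: visit1.values, 1: visit2.values}
    try:
        rows = [
            matrices[int(v)][lookup[int(v)][s]]
            for s, v in zip(df[table.subject_col], df[table.visit_col])
        ]
    except KeyError as exc:
        raise ValueError(f"table row references subject absent from its visit matrix: {exc}") from exc
    Y = np.asarray(rows)
    V = visit1.n_vertices

    names = ["intercept"] + list(fixed_effects)
    result = LMMResult(effects=names)
    betas = {e: np.empty(V) for e in names}
    ses = {e: np.empty(V) for e in names}
    ps = {e: np.empty(V) for e in names}
    s2b = np.empty(V)
    s2e = np.empty(V)
    rho_grid = np.concatenate([[0.0], np.geomspace(1e-4, RHO_MAX, 60)])
    for v in range(V):
        row = fit_vertex_lmm(table_s, Y[:, v], fixed_effects, rho_grid=rho_grid)
        for e in names:
            betas[e][v] = row["beta"][e]
            ses[e][v] = row["se"][e]
            ps[e][v] = row["p"][e]
        s2b[v] = row["sigma2_b"]
        s2e[v] = row["sigma2_e"]
    result.beta, result.se, result.p = betas, ses, ps
    result.sigma2_b, result.sigma2_e = s2b, s2e
    result.sig = {e: bh_fdr(ps[e], fdr_q) for e in names}

    visit_col = table.visit_col
    if visit_col in names:
        mask = result.sig[visit_col]
        b = betas[visit_col]
        pos = mask & (b > 0)
        neg = mask & (b < 0)
        result.visit_summary = {
            "median_increase": float(np.median(b[pos])) if pos.any() else np.nan,
            "median_decrease": float(np.median(b[neg])) if neg.any() else np.nan,
            "n_pos": int(pos.sum()),
            "n_neg": int(neg.sum()),
        }
    return result
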