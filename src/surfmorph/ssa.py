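"""Statistical shape analysis: sparse PCA of cohort thickness fields.

The subjects x vertices thickness matrix is median-centred per vertex
(a robust location estimate) and decomposed into k sparse components by
rank-1 alternating regression with an L1 (soft-threshold) penalty on the
loadings and projection deflation between components. With the penalty at
zero the iteration is exact power iteration, so the model reduces to
classical PCA — the verifiable anchor for the implementation. Scores are
low-dimensional shape coordinates used downstream as survival covariates;
loadings localise each mode on the surface, and ``shape_at_sd``
reconstructs the thickness field at +/- t score standard deviations for
interpretation.

Explained variance of sparse (correlated) components uses the adjusted,
QR-based definition (regression-projection variance), which avoids double
counting shared variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .thickness import CohortMatrix

__all__ = ["SPCAModel", "fit_spca", "transform", "shape_at_sd"]

_MAX_ITER = 2000
_TOL = 1e-12


@dataclass
class SPCAModel:
    """Sparse loadings, scores and variance bookkeeping."""

    loadings: np.ndarray  # (V, k), unit-norm columns
    scores: np.ndarray  # (n, k)
    center: np.ndarray  # per-vertex median
    component_variance: np.ndarray  # (k,) adjusted variances
    explained_variance_ratio: np.ndarray  # (k,) fractions of total variance
    sparsity: float
    total_variance: float
    sparsity_fraction: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def cumulative_explained(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)

    def score_sd(self) -> np.ndarray:
        return self.scores.std(axis=0, ddof=1)


def _soft_threshold(x: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def _rank1_sparse(X: np.ndarray, lam: float, v0: np.ndarray) -> np.ndarray:
    """Alternating regression for one sparse loading vector (unit norm).

    u = X v;  v <- soft_threshold(X'u, lam * ||X'u||_inf), renormalised.
    lam = 0 is exact power iteration on X'X.
    """
    v = v0 / np.linalg.norm(v0)
    for _ in range(_MAX_ITER):
        u = X @ v
        w = X.T @ u
        if lam > 0:
            w = _soft_threshold(w, lam * np.abs(w).max())
        nrm = np.linalg.norm(w)
        if nrm == 0:  # fully thresholded: fall back to dense direction
            w = X.T @ u
            nrm = np.linalg.norm(w)
            if nrm == 0:
                return v
        w = w / nrm
        if np.linalg.norm(w - v) < _TOL or np.linalg.norm(w + v) < _TOL:
            v = w
            break
        v = w
    return v


def _adjusted_variance(Xc: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """QR-adjusted component variances (sequential, no double counting)."""
    S = Xc @ loadings
    _, R = np.linalg.qr(S)
    return np.diag(R) ** 2 / (Xc.shape[0] - 1)


def fit_spca(
    matrix: CohortMatrix | np.ndarray,
    k: int,
    sparsity: float = 0.0,
    seed: int = 0,
    winsorize_mads: float | None = None,
) -> SPCAModel:
    """Fit a k-component sparse PCA to the cohort thickness matrix.

    Parameters
    ----------
    sparsity : relative soft-threshold level in [0, 1); the L1 threshold
        for each loading update is ``sparsity * max|gradient|``, so 0 is
        classical PCA and values near 1 force very sparse loadings.
    winsorize_mads : optionally clip scores at this many median absolute
        deviations from their median (robustness to residual outliers).

    Loadings have unit L2 norm with a deterministic sign convention
    (largest-magnitude entry positive); deflation is by projection.
    """
    X = matrix.values if isinstance(matrix, CohortMatrix) else np.asarray(matrix, float)
    n, V = X.shape
    if k > min(n - 1, V):
        raise ValueError(f"k={k} exceeds min(n-1, V) = {min(n - 1, V)}")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    if not (0 <= sparsity < 1):
        raise ValueError("sparsity must lie in [0, 1)")
    center = np.median(X, axis=0)
    Xc = X - center
    total_variance = float(np.einsum("ij,ij->", Xc, Xc) / (n - 1))

    rng = np.random.default_rng(seed)
    loadings = np.empty((V, k))
    Xd = Xc.copy()
    for j in range(k):
        # deterministic warm start: leading right singular direction of Xd
        v0 = Xd.T @ Xd @ rng.standard_normal(V)
        if np.linalg.norm(v0) == 0:
            v0 = rng.standard_normal(V)
        v = _rank1_sparse(Xd, sparsity, v0)
        i_max = int(np.argmax(np.abs(v)))
        if v[i_max] < 0:
            v = -v
        loadings[:, j] = v
        u = Xd @ v
        Xd = Xd - np.outer(u, v)  # projection deflation
    scores = Xc @ loadings
    if winsorize_mads is not None:
        med = np.median(scores, axis=0)
        mad = np.median(np.abs(scores - med), axis=0)
        mad = np.where(mad == 0, 1.0, mad) * 1.4826
        lo = med - winsorize_mads * mad
        hi = med + winsorize_mads * mad
        scores = np.clip(scores, lo, hi)
    comp_var = _adjusted_variance(Xc, loadings)
    evr = comp_var / total_variance if total_variance > 0 else np.zeros(k)
    sparsity_fraction = (loadings == 0).mean(axis=0)
    return SPCAModel(
        loadings=loadings,
        scores=scores,
        center=center,
        component_variance=comp_var,
        explained_variance_ratio=evr,
        sparsity=sparsity,
        total_variance=total_variance,
        sparsity_fraction=sparsity_fraction,
    )


def transform(model: SPCAModel, matrix: CohortMatrix | np.ndarray) -> np.ndarray:
    """Project new subjects onto the fitted components.

    ``scores = (X - center) @ loadings``; reproduces the stored training
    scores when applied to the training matrix (without winsorization).
    """
    X = matrix.values if isinstance(matrix, CohortMatrix) else np.asarray(matrix, float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.loadings.shape[0]:
        raise ValueError(
            f"vertex count mismatch: matrix has {X.shape[1]}, model has {model.loadings.shape[0]}"
        )
    return (X - model.center) @ model.loadings


def shape_at_sd(model: SPCAModel, mean_field: np.ndarray, component: int, t: float) -> np.ndarray:
    """Thickness field at ``t`` score standard deviations along one mode.

    ``field = mean + t * SD(score_j) * loading_j`` — the +/-3 SD
    reconstructions used to visualise what each component means
    anatomically.
    """
    if abs(t) > 5:
        raise ValueError("|t| > 5 standard deviations is outside the sane visualisation range")
    if not (0 <= component < model.k):
        raise ValueError(f"component {component} out of range [0, {model.k})")
    mean_field = np.asarray(mean_field, dtype=float)
    sd = model.score_sd()[component]
    return mean_field + t * sd * model.loadings[:, component]
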