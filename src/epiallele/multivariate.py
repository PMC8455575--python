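"""NIPALS principal component analysis with missing-value support.

NIPALS (nonlinear iterative partial least squares) extracts principal
components one at a time by alternating regressions between a score vector
t and a loading vector p, deflating the matrix after each component.
Because every inner product is taken over observed entries only, the
algorithm tolerates missing values natively — the property that makes it
the standard choice for methylation feature matrices where some sample x
feature cells fail QC.

Columns are mean-centered and scaled to unit variance (n-1 standard
deviation) before extraction, so features on different scales (percent
methylation, correlations, epipolymorphism) contribute comparably.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["PCAResult", "nipals_pca", "build_feature_matrix"]


@dataclasses.dataclass(frozen=True)
class PCAResult:
    """Scores, unit-norm loadings and explained-variance fractions.

    Sign convention: within each component the largest-magnitude loading is
    positive, so results are deterministic.  ``converged`` flags per
    component whether the score iteration met ``tol`` before ``max_iter``;
    non-convergence is carried here as a warning, never silently dropped.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    column_mean: np.ndarray
    column_scale: np.ndarray
    converged: tuple[bool, ...]
    n_iterations: tuple[int, ...]
    rows: tuple | None = None
    columns: tuple | None = None


def nipals_pca(
    X,
    n_components: int = 2,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> PCAResult:
    """NIPALS PCA of a (possibly incomplete) sample x feature matrix.

    Missing entries (NaN) are skipped in every inner product.  Raises on
    zero-variance or all-missing columns (naming the column) and when
    ``n_components`` exceeds ``min(n_rows, n_cols)``.
    """
    rows = cols = None
    if isinstance(X, pd.DataFrame):
        rows, cols = tuple(X.index), tuple(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.array(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("X must be 2-D with at least 2 rows and 2 columns")
    n, m = X.shape
    if not (1 <= n_components <= min(n, m)):
        raise ValueError(
            f"n_components must be in [1, {min(n, m)}], got {n_components}"
        )
    mask = np.isfinite(X)
    for j in range(m):
        name = cols[j] if cols is not None else j
        obs = X[mask[:, j], j]
        if obs.size == 0:
            raise ValueError(f"column {name!r} is entirely missing")
        if obs.size < 2 or np.std(obs, ddof=1) == 0:
            raise ValueError(f"column {name!r} has zero variance after centering")

    mean = np.array([X[mask[:, j], j].mean() for j in range(m)])
    scale = np.array([np.std(X[mask[:, j], j], ddof=1) for j in range(m)])
    R = np.where(mask, (X - mean) / scale, 0.0)
    total_ss = float(np.sum(R**2))

    scores = np.zeros((n, n_components))
    loadings = np.zeros((m, n_components))
    evr = np.zeros(n_components)
    converged: list[bool] = []
    iters: list[int] = []

    for comp in range(n_components):
        ss_before = float(np.sum(R**2))
        t = R[:, int(np.argmax(np.sum(R**2, axis=0)))].copy()
        if not np.any(t):
            t = np.ones(n)
        ok = False
        it = 0
        for it in range(1, max_iter + 1):
            denom_p = mask.T.astype(float) @ (t**2)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = (R.T @ t) / np.where(denom_p > 0, denom_p, np.nan)
            p = np.nan_to_num(p)
            norm = np.linalg.norm(p)
            if norm == 0:
                break
            p /= norm
            denom_t = mask.astype(float) @ (p**2)
            with np.errstate(invalid="ignore", divide="ignore"):
                t_new = (R @ p) / np.where(denom_t > 0, denom_t, np.nan)
            t_new = np.nan_to_num(t_new)
            delta = np.linalg.norm(t_new - t)
            t = t_new
            if delta < tol * max(np.linalg.norm(t), 1e-30):
                ok = True
                break
        # deterministic sign: largest-magnitude loading positive
        pivot = int(np.argmax(np.abs(p)))
        if p[pivot] < 0:
            p = -p
            t = -t
        scores[:, comp] = t
        loadings[:, comp] = p
        R = np.where(mask, R - np.outer(t, p), 0.0)
        evr[comp] = (ss_before - float(np.sum(R**2))) / total_ss if total_ss > 0 else 0.0
        converged.append(ok)
        iters.append(it)

    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=evr,
        column_mean=mean,
        column_scale=scale,
        converged=tuple(converged),
        n_iterations=tuple(iters),
        rows=rows,
        columns=cols,
    )


def build_feature_matrix(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-sample feature matrix from a per-sample x region summary table.

    Rows are samples; columns are {mean methylation, mean pairwise
    correlation, epipolymorphism} x region.  QC-failed cells stay NaN (the
    NIPALS fit skips them).
    """
    stats = ["mean_methylation", "mean_pairwise_r", "epipolymorphism"]
    wide = summary.pivot(index="sample_id", columns="region_id", values=stats)
    wide.columns = [f"{stat}__{region}" for stat, region in wide.columns]
    return wide.sort_index(axis=1).sort_index()
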