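"""Anatomical factor analysis: correlation-matrix PCA with Varimax rotation.

Regions whose adjusted volumes covary across participants are grouped by a
principal component analysis of the inter-region correlation matrix (volumes
are standardized first — regions differ by orders of magnitude).  The
retained components are rotated to simple structure with the Varimax
criterion, reported as a thresholded loading table, and the per-participant
component scores are regressed on age, fitness and their interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regional import roi_partial_betas, roi_correlations


@dataclass
class FactorSolution:
    """Loadings, eigenvalues and component scores of a (rotated) PCA."""

    loadings: pd.DataFrame = field(repr=False)     # region x factor
    eigenvalues: np.ndarray = field(repr=False)    # all, descending
    scores: pd.DataFrame = field(repr=False)       # participant x factor
    rotation: np.ndarray | None = field(default=None, repr=False)
    k: int = 0

    @property
    def variance_explained(self) -> np.ndarray:
        """Per-factor share of total variance (sum of squared loadings / p)."""
        ssl = (self.loadings.to_numpy() ** 2).sum(axis=0)
        return ssl / len(self.loadings)

    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1)


def fit_pca(volumes: pd.DataFrame, region_set: list[str] | None = None, k: int | None = None) -> FactorSolution:
    """PCA of the inter-region correlation matrix.

    Loadings are eigenvectors scaled by sqrt(eigenvalue) (so they are the
    correlations between regions and components); scores are standardized
    (unit-variance) principal component scores.  ``k`` limits the retained
    columns (all by default).
    """
    regions = region_set if region_set is not None else list(volumes.columns)
    data = volumes[regions].to_numpy(float)
    if not np.isfinite(data).all():
        raise ValueError("non-finite volumes in factor-analysis input")
    n, p = data.shape
    if n <= 2:
        raise ValueError("need more than 2 participants")
    z = (data - data.mean(axis=0)) / data.std(axis=0, ddof=1)
    corr = (z.T @ z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    k_keep = k if k is not None else p
    if k_keep > p:
        raise ValueError(f"k={k_keep} exceeds region count {p}")
    # sign convention: largest-|loading| entry of each column positive
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        load = eigvec[:, :k_keep] * np.sqrt(eigval[:k_keep])
        score = np.where(eigval[:k_keep] > 0, z @ eigvec[:, :k_keep] / np.sqrt(eigval[:k_keep] * 1.0), 0.0)
    cols = [f"F{j + 1}" for j in range(k_keep)]
    return FactorSolution(
        loadings=pd.DataFrame(load, index=regions, columns=cols),
        eigenvalues=eigval,
        scores=pd.DataFrame(score, index=volumes.index, columns=cols),
        rotation=None,
        k=k_keep,
    )


def select_components(eigenvalues: np.ndarray, k_override: int | None = None) -> int:
    """Choose the component count: explicit override, else scree elbow.

    The elbow heuristic keeps the components before the largest drop in
    successive eigenvalue differences (the kink in the scree plot).
    """
    ev = np.asarray(eigenvalues, float)
    if np.any(np.diff(ev) > 1e-12):
        raise ValueError("eigenvalues must be sorted descending")
    if k_override is not None:
        if not 1 <= k_override <= len(ev):
            raise ValueError(f"k={k_override} out of range 1..{len(ev)}")
        return int(k_override)
    drops = -np.diff(ev)
    return int(np.argmax(drops) + 1)


def scree_table(eigenvalues: np.ndarray) -> pd.DataFrame:
    ev = np.asarray(eigenvalues, float)
    return pd.DataFrame(
        {
            "component": np.arange(1, len(ev) + 1),
            "eigenvalue": ev,
            "proportion": ev / ev.sum(),
            "cumulative": np.cumsum(ev) / ev.sum(),
        }
    )


def _varimax_criterion(L: np.ndarray) -> float:
    """Raw varimax objective: sum over factors of var of squared loadings."""
    sq = L**2
    return float(np.sum(sq.var(axis=0)))


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation by iterative SVD updates.

    Returns (rotated loadings, orthogonal rotation matrix).  With Kaiser
    normalization rows are scaled to unit communality during the rotation
    and rescaled afterwards.  Non-convergence warns and returns the best
    iterate.
    """
    L = np.asarray(loadings, float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    h = np.sqrt((L**2).sum(axis=1))
    if kaiser_normalize:
        h_safe = np.where(h > 0, h, 1.0)
        L = L / h_safe[:, None]
    R = np.eye(k)
    d_old = 0.0
    converged = False
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        d = s.sum()
        if d_old != 0 and (d - d_old) / d_old < tol:
            converged = True
            break
        d_old = d
    if not converged:
        warnings.warn("varimax rotation did not converge; returning best iterate")
    Lr = L @ R
    if kaiser_normalize:
        Lr = Lr * np.where(h > 0, h, 1.0)[:, None]
    return Lr, R


def varimax_rotate(solution: FactorSolution, k: int | None = None, kaiser_normalize: bool = True) -> FactorSolution:
    """Rotate the first ``k`` components of a PCA solution to simple structure.

    k = 1 returns the truncated solution unchanged.  Scores are rotated with
    the same orthogonal matrix, preserving unit variances.
    """
    k = k if k is not None else solution.k
    L = solution.loadings.to_numpy()[:, :k]
    S = solution.scores.to_numpy()[:, :k]
    if k == 1:
        Lr, R = L, np.eye(1)
        Sr = S
    else:
        Lr, R = varimax(L, kaiser_normalize=kaiser_normalize)
        Sr = S @ R
    # column sign convention, applied jointly to loadings and scores
    for j in range(k):
        i = np.argmax(np.abs(Lr[:, j]))
        if Lr[i, j] < 0:
            Lr[:, j] = -Lr[:, j]
            Sr[:, j] = -Sr[:, j]
    cols = [f"F{j + 1}" for j in range(k)]
    return FactorSolution(
        loadings=pd.DataFrame(Lr, index=solution.loadings.index, columns=cols),
        eigenvalues=solution.eigenvalues,
        scores=pd.DataFrame(Sr, index=solution.scores.index, columns=cols),
        rotation=R,
        k=k,
    )


def loading_report(
    solution: FactorSolution,
    report_threshold: float = 0.3,
    high_threshold: float = 0.5,
) -> pd.DataFrame:
    """Thresholded loading table: per factor, |loading| >= threshold.

    Rows are sorted within each factor by descending |loading|; negative
    loadings keep their sign; |loading| > ``high_threshold`` is marked high.
    Factors with no loading over the threshold yield a notice row.
    """
    rows = []
    for col in solution.loadings.columns:
        vals = solution.loadings[col]
        sel = vals[vals.abs() >= report_threshold]
        sel = sel.reindex(sel.abs().sort_values(ascending=False).index)
        if sel.empty:
            rows.append({"factor": col, "region": "(none over threshold)",
                         "loading": np.nan, "high": False})
            continue
        for region, v in sel.items():
            rows.append({"factor": col, "region": region, "loading": float(v),
                         "high": bool(abs(v) > high_threshold)})
    return pd.DataFrame(rows)


def score_regression(solution: FactorSolution, design: pd.DataFrame) -> pd.DataFrame:
    """Regress each factor's component scores on age/fitness/interaction.

    Emits raw correlations and standardized coefficients side by side,
    mirroring the per-region association table but with factors as targets.
    """
    scores = solution.scores
    raw = roi_correlations(scores, design)
    betas = roi_partial_betas(scores, design)
    out = raw.drop(columns="flagged").join(betas.drop(columns="flagged"), how="inner")
    out.index.name = "factor"
    return out
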