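"""PCA validation stage: sampling adequacy, Kaiser retention, varimax.

Used to cross-check the correlation-network communities: Bartlett's test
of sphericity and the Kaiser-Meyer-Olkin measure of sampling adequacy
establish that the variable set is factorable; correlation-matrix PCA with
Kaiser's eigenvalue-greater-than-one retention rule and Kaiser-normalized
varimax rotation then yields interpretable variable clusters, and patient
component scores (regression/Thurstone method) feed the survival stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = ["PcaResult", "bartlett_sphericity", "kmo_msa", "pca_varimax"]


@dataclass(frozen=True)
class PcaResult:
    eigenvalues: np.ndarray          # all p, descending
    loadings: pd.DataFrame           # variables x retained components
    rotated_loadings: pd.DataFrame   # same shape, varimax-rotated
    component_scores: pd.DataFrame   # patients x retained components
    kmo_overall: float
    kmo_per_variable: dict[str, float]
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    retained: int


def bartlett_sphericity(
    corr_matrix: np.ndarray, n: int
) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R), df = p(p-1)/2.
    """
    R = np.asarray(corr_matrix, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("corr_matrix must be square and symmetric")
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix is singular (det <= 0)")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    chi2 = max(chi2, 0.0)
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), df, pval


def kmo_msa(
    corr_matrix: np.ndarray, variables: Sequence[str] | None = None
) -> tuple[float, dict[str, float]]:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    overall = sum r^2 / (sum r^2 + sum q^2) over off-diagonal entries,
    where q are the anti-image partial correlations from inv(R); the
    per-variable MSA applies the same ratio row-wise.
    """
    R = np.asarray(corr_matrix, dtype=float)
    p = R.shape[0]
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not invertible") from exc
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    Q = -Rinv / d  # partial correlations (anti-image)
    off = ~np.eye(p, dtype=bool)
    r2 = R[off] ** 2
    q2 = Q[off] ** 2
    overall = float(r2.sum() / (r2.sum() + q2.sum()))
    names = list(variables) if variables is not None else [str(i) for i in range(p)]
    per_var = {}
    for i in range(p):
        mask = off[i]
        ri2 = (R[i, mask] ** 2).sum()
        qi2 = (Q[i, mask] ** 2).sum()
        per_var[names[i]] = float(ri2 / (ri2 + qi2))
    return overall, per_var


def _kaiser_normalized_varimax(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Varimax with Kaiser row-normalization; returns (rotated, rotation)."""
    if A.shape[1] == 1:
        return A.copy(), np.eye(1)
    h = np.sqrt((A**2).sum(axis=1))
    h = np.where(h > 0, h, 1.0)
    L, T = rotate_factors(A / h[:, None], "varimax")
    return L * h[:, None], T


def pca_varimax(
    data: pd.DataFrame,
    variables: Sequence[str] | None = None,
    kaiser_cutoff: float = 1.0,
) -> PcaResult:
    """Correlation-matrix PCA with Kaiser retention and varimax rotation.

    Rows with any missing value among ``variables`` are dropped for the
    decomposition; component scores are computed for the retained rows by
    the regression (Thurstone) method, scores = Z R^-1 L_rot. Score and
    loading signs are fixed so each component's largest-|loading| variable
    loads positively.
    """
    if variables is None:
        variables = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    X = data[variables].dropna()
    n, p = X.shape
    if n <= p:
        import warnings

        warnings.warn(f"n={n} <= p={p}: PCA is ill-conditioned", stacklevel=2)
    Z = (X - X.mean()) / X.std(ddof=1)
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    chi2, df, bart_p = bartlett_sphericity(R, n)
    kmo_overall, kmo_per_var = kmo_msa(R, variables)

    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    retained = int((eigval > kaiser_cutoff).sum())
    if retained < 1:
        raise ValueError(
            f"no eigenvalue exceeds the Kaiser cutoff {kaiser_cutoff}"
        )
    comp_names = [f"PC{i + 1}" for i in range(retained)]
    A = eigvec[:, :retained] * np.sqrt(eigval[:retained])
    L, _ = _kaiser_normalized_varimax(A)

    # sign convention: dominant variable of each component loads positively
    for j in range(retained):
        i_max = int(np.argmax(np.abs(L[:, j])))
        if L[i_max, j] < 0:
            L[:, j] = -L[:, j]
    for j in range(retained):
        i_max = int(np.argmax(np.abs(A[:, j])))
        if A[i_max, j] < 0:
            A[:, j] = -A[:, j]

    scores = Z.to_numpy() @ np.linalg.solve(R, L)
    return PcaResult(
        eigenvalues=eigval,
        loadings=pd.DataFrame(A, index=variables, columns=comp_names),
        rotated_loadings=pd.DataFrame(L, index=variables, columns=comp_names),
        component_scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        kmo_overall=kmo_overall,
        kmo_per_variable=kmo_per_var,
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=bart_p,
        retained=retained,
    )
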