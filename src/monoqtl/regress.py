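"""Vectorized least-squares helpers used by the scan-style analyses.

These cover the repetitive many-columns-at-once fits (thousands of genes
against one design matrix); one-off models elsewhere in the package go
through statsmodels OLS.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def design_matrix(*columns: np.ndarray) -> np.ndarray:
    """Stack an intercept plus the given columns into an (n, k) design."""
    cols = [np.ones(len(columns[0]))] + [np.asarray(c, dtype=float) for c in columns]
    return np.column_stack(cols)


def is_collinear(X: np.ndarray, tol: float = 1e-8) -> bool:
    return np.linalg.matrix_rank(X, tol=tol * max(X.shape)) < X.shape[1]


def ols_scan(Y: np.ndarray, X: np.ndarray, coef_index: int = 1
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Regress every column of Y on X; return (beta, t, p) for one coefficient.

    Y is (n, m); X is (n, k) including the intercept. The t statistic and
    two-sided P refer to ``coef_index``. Columns of Y with zero residual
    variance get beta as fitted, t=0, p=1.
    """
    Y = np.asarray(Y, dtype=float)
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta_all = xtx_inv @ (X.T @ Y)  # (k, m)
    resid = Y - X @ beta_all
    df = n - k
    sigma2 = (resid ** 2).sum(axis=0) / df
    # degenerate columns (zero dependent variance up to round-off)
    degenerate = Y.var(axis=0) <= 1e-24 * np.maximum(
        (Y ** 2).mean(axis=0), 1e-300)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[coef_index, coef_index], 0.0))
    beta = np.where(degenerate, 0.0, beta_all[coef_index])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where((se > 0) & ~degenerate, beta / se, 0.0)
    p = np.where((se > 0) & ~degenerate, 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    return beta, t, p


def residualize(v: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of v (1-D or 2-D columns) after projection on X."""
    v = np.asarray(v, dtype=float)
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ coef


def partial_f_p(y: np.ndarray, X_base: np.ndarray, candidates: np.ndarray
                ) -> np.ndarray:
    """P-value of each candidate column when added alone to the base model.

    Uses the partial-correlation identity: with ry and rz the residuals of
    y and the candidate on the base design, the add-one t² equals
    df·r²/(1−r²) with df = n − k_base − 1, which is the 1-df partial F.
    """
    n, k = X_base.shape
    ry = residualize(y, X_base)
    RZ = residualize(candidates, X_base)
    df = n - k - 1
    sy = np.sqrt((ry ** 2).sum())
    sz = np.sqrt((RZ ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (RZ.T @ ry) / (sy * sz)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    f = df * r ** 2 / np.maximum(1.0 - r ** 2, np.finfo(float).tiny)
    return stats.f.sf(f, 1, df)


def nested_f_test(y: np.ndarray, X_full: np.ndarray, X_reduced: np.ndarray
                  ) -> tuple[float, float]:
    """F-test of the full model against the nested reduced model."""
    y = np.asarray(y, dtype=float)
    rss_f = (residualize(y, X_full) ** 2).sum()
    rss_r = (residualize(y, X_reduced) ** 2).sum()
    df1 = X_full.shape[1] - X_reduced.shape[1]
    df2 = len(y) - X_full.shape[1]
    if df1 <= 0 or df2 <= 0:
        raise ValueError("full model must strictly nest the reduced model")
    if rss_f <= 0:
        return np.inf, 0.0
    f = ((rss_r - rss_f) / df1) / (rss_f / df2)
    return float(f), float(stats.f.sf(f, df1, df2))
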