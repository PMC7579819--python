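"""Small shared least-squares helpers (coefficients, SEs, t-based p-values).

Designs here are tiny (tens of columns at most), so plain normal-equation /
lstsq solves are both exact and fast; statsmodels is reserved for places
where a full results object is reported.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def ols(X: np.ndarray, y: np.ndarray, add_intercept: bool = True):
    """OLS fit returning (beta, se, tvals, pvals, df_resid, rss).

    ``beta`` excludes the intercept when ``add_intercept`` (the intercept is
    prepended internally and stripped from the outputs).
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, float)
    n = len(y)
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
    k = X.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - k
    if df <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    rss = float(resid @ resid)
    sigma2 = rss / df
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    if add_intercept:
        return beta[1:], se[1:], tvals[1:], pvals[1:], df, rss
    return beta, se, tvals, pvals, df, rss


def slope_test(x: np.ndarray, y: np.ndarray):
    """Simple regression y ~ x: (beta, se, t, two-sided p, df)."""
    beta, se, t, p, df, _ = ols(x, y)
    return float(beta[0]), float(se[0]), float(t[0]), float(p[0]), df


def f_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Regression F-statistic of y on a single regressor (equals t^2)."""
    _, _, t, _, _, _ = ols(x, y)
    return float(t[0] ** 2)


def ci_from_fit(beta: float, se: float, df: int, level: float = 0.95):
    q = stats.t.ppf(0.5 + level / 2, df)
    return beta - q * se, beta + q * se
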