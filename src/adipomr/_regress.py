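"""Vectorised single-predictor regression kernels.

Per-SNP association scans and within-stratum instrument regressions need tens of
thousands of two-parameter (intercept + slope) fits; these closed-form OLS and
Newton-Raphson logistic kernels run them as array operations. Multi-covariate
models elsewhere in the package go through statsmodels.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "simple_ols",
    "gwas_linear",
    "gwas_logistic",
    "paired_simple_ols",
    "paired_simple_logistic",
    "wls_line",
]


def simple_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and SE of the OLS regression of ``y`` on ``x`` (with intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx <= 0:
        raise ValueError("predictor has zero variance")
    beta = (xc @ y) / sxx
    resid = y - y.mean() - beta * xc
    sigma2 = (resid @ resid) / (n - 2)
    return float(beta), float(np.sqrt(sigma2 / sxx))


def gwas_linear(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column simple linear regression of ``y`` on each column of ``G``.

    Returns (betas, ses), each of length M = G.shape[1].
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = G.shape[0]
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    if np.any(sxx <= 0):
        raise ValueError("monomorphic genotype column")
    beta = (Gc.T @ yc) / sxx
    # residual sum of squares without forming per-SNP residual matrices
    syy = yc @ yc
    rss = syy - beta**2 * sxx
    sigma2 = rss / (n - 2)
    return beta, np.sqrt(sigma2 / sxx)


def gwas_logistic(
    G: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column logistic regression (intercept + dosage) of binary ``y``.

    Newton-Raphson on the 2-parameter model for every column simultaneously.
    Returns per-allele log-odds slopes and their Wald SEs.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    ybar = y.mean()
    if ybar <= 0 or ybar >= 1:
        raise ValueError("outcome has no variation")
    a = np.full(m, np.log(ybar / (1 - ybar)))
    b = np.zeros(m)
    for _ in range(max_iter):
        eta = a[None, :] + G * b[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        r = y[:, None] - p
        g_a = r.sum(axis=0)
        g_b = np.einsum("ij,ij->j", r, G)
        h_aa = w.sum(axis=0)
        h_ab = np.einsum("ij,ij->j", w, G)
        h_bb = np.einsum("ij,ij,ij->j", w, G, G)
        det = h_aa * h_bb - h_ab**2
        det = np.where(det <= 0, np.nan, det)
        da = (h_bb * g_a - h_ab * g_b) / det
        db = (h_aa * g_b - h_ab * g_a) / det
        # guard against overshoot in near-separated strata
        np.clip(da, -5, 5, out=da)
        np.clip(db, -5, 5, out=db)
        a += da
        b += db
        if np.nanmax(np.abs(da)) < tol and np.nanmax(np.abs(db)) < tol:
            break
    eta = a[None, :] + G * b[None, :]
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    h_aa = w.sum(axis=0)
    h_ab = np.einsum("ij,ij->j", w, G)
    h_bb = np.einsum("ij,ij,ij->j", w, G, G)
    det = h_aa * h_bb - h_ab**2
    with np.errstate(invalid="ignore", divide="ignore"):
        se_b = np.sqrt(h_aa / det)
    return b, se_b


def paired_simple_ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise simple OLS: regress Y[i, :] on X[i, :] for every row i.

    Used by the within-stratum bootstrap, where each resample has its own
    predictor and response. Returns (slopes, ses) of length B.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", Xc, Xc)
    beta = np.einsum("ij,ij->i", Xc, Yc) / sxx
    rss = np.einsum("ij,ij->i", Yc, Yc) - beta**2 * sxx
    sigma2 = rss / (n - 2)
    return beta, np.sqrt(sigma2 / sxx)


def paired_simple_logistic(
    X: np.ndarray,
    Y: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise 2-parameter logistic regression of binary Y[i, :] on X[i, :]."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    ybar = Y.mean(axis=1)
    bad = (ybar <= 0) | (ybar >= 1)
    ybar = np.where(bad, 0.5, ybar)
    a = np.log(ybar / (1 - ybar))
    b = np.zeros_like(a)
    for _ in range(max_iter):
        eta = a[:, None] + X * b[:, None]
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        r = Y - p
        g_a = r.sum(axis=1)
        g_b = np.einsum("ij,ij->i", r, X)
        h_aa = w.sum(axis=1)
        h_ab = np.einsum("ij,ij->i", w, X)
        h_bb = np.einsum("ij,ij,ij->i", w, X, X)
        det = h_aa * h_bb - h_ab**2
        det = np.where(det <= 0, np.nan, det)
        da = np.clip((h_bb * g_a - h_ab * g_b) / det, -5, 5)
        db = np.clip((h_aa * g_b - h_ab * g_a) / det, -5, 5)
        a += da
        b += db
        if np.nanmax(np.abs(da)) < tol and np.nanmax(np.abs(db)) < tol:
            break
    eta = a[:, None] + X * b[:, None]
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    h_aa = w.sum(axis=1)
    h_ab = np.einsum("ij,ij->i", w, X)
    h_bb = np.einsum("ij,ij,ij->i", w, X, X)
    det = h_aa * h_bb - h_ab**2
    with np.errstate(invalid="ignore", divide="ignore"):
        se_b = np.sqrt(h_aa / det)
    b = np.where(bad, np.nan, b)
    se_b = np.where(bad, np.nan, se_b)
    return b, se_b


def wls_line(
    x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Weighted least squares of ``y`` on ``x`` with intercept.

    Returns (intercept, slope, covariance matrix). The covariance is the
    model-based (X'WX)^-1 with unit dispersion; callers apply any
    overdispersion scaling themselves.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    sw = w.sum()
    swx = w @ x
    swxx = w @ (x * x)
    det = sw * swxx - swx**2
    if det <= 1e-12 * sw * swxx:
        raise ValueError("design is collinear: predictor has (weighted) zero variance")
    swy = w @ y
    swxy = w @ (x * y)
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    cov = np.array([[swxx, -swx], [-swx, sw]]) / det
    return float(intercept), float(slope), cov
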