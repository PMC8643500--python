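"""Phenotype transformations and covariate-adjusted observational models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import ndtri

from .results import ObservationalEstimate
from .simulate import Cohort

Z95 = stats.norm.ppf(0.975)


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal (Blom) transform.

    z_i = Phi^-1((r_i - 3/8) / (n + 1/4)) with average ranks for ties. The
    output preserves rank order, has mean ~0 and SD ~1, and is invariant to
    any strictly monotone transform of the input.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-d vector with at least 2 values")
    if not np.all(np.isfinite(values)):
        raise ValueError("input contains non-finite values")
    if np.ptp(values) == 0:
        raise ValueError("all values identical; ranks undefined")
    ranks = stats.rankdata(values, method="average")
    return ndtri((ranks - 0.375) / (values.size + 0.25))


class PerfectSeparationError(RuntimeError):
    """Logistic fit abandoned: outcome perfectly separated by the design."""


def _design(
    df: pd.DataFrame, exposure_col: str, covariates: list[str]
) -> pd.DataFrame:
    """Exposure plus covariates, categoricals dummy-coded."""
    X = pd.DataFrame({exposure_col: df[exposure_col].to_numpy()})
    for c in covariates:
        col = df[c]
        if col.dtype == object or str(col.dtype) == "category" or c == "centre":
            dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True)
            for d in dummies.columns:
                X[d] = dummies[d].to_numpy().astype(float)
        else:
            X[c] = col.to_numpy().astype(float)
    return sm.add_constant(X, has_constant="add")


def fit_observational(
    cohort: Cohort,
    outcome: str,
    exposure: str = "exposure",
    covariates: tuple[str, ...] = ("age", "sex", "centre", "tdi", "smoking"),
    stratum: str = "all",
) -> ObservationalEstimate:
    """Logistic (binary) or linear (continuous) regression of an outcome on
    the exposure plus covariates; the effect is reported per 1-SD exposure
    (odds ratio for binary outcomes). Sex-stratified fits drop sex from the
    adjustment set.
    """
    df = cohort.covariates.copy()
    df[exposure] = cohort.exposure if exposure == "exposure" else cohort.exposure_raw
    df[outcome] = cohort.outcomes[outcome].to_numpy()
    covariates = tuple(covariates)
    if stratum == "male":
        df = df[df["sex"] == 1]
    elif stratum == "female":
        df = df[df["sex"] == 0]
    elif stratum != "all":
        raise ValueError(f"unknown stratum {stratum!r}")
    if stratum != "all":
        covariates = tuple(c for c in covariates if c != "sex")
    df = df.dropna(subset=[outcome])

    y = df[outcome].to_numpy().astype(float)
    X = _design(df, exposure, list(covariates))
    binary = set(np.unique(y)) <= {0.0, 1.0}
    if binary:
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
        except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
            raise PerfectSeparationError(str(exc)) from exc
        if not fit.mle_retvals.get("converged", True):
            raise RuntimeError("logistic fit did not converge")
        beta = fit.params[exposure]
        se = fit.bse[exposure]
        est, lo, hi = np.exp([beta, beta - Z95 * se, beta + Z95 * se])
        scale = "odds ratio per SD exposure"
        n_cases = int(y.sum())
        n_controls = int(y.size - n_cases)
    else:
        fit = sm.OLS(y, X).fit()
        beta = fit.params[exposure]
        se = fit.bse[exposure]
        est, lo, hi = beta, beta - Z95 * se, beta + Z95 * se
        scale = "slope per SD exposure"
        n_cases = n_controls = None
    return ObservationalEstimate(
        outcome=outcome,
        exposure=exposure,
        stratum=stratum,
        scale=scale,
        effect=float(est),
        ci_low=float(lo),
        ci_high=float(hi),
        p=float(fit.pvalues[exposure]),
        n_total=int(y.size),
        n_cases=n_cases,
        n_controls=n_controls,
        adjustment=covariates,
    )
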