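"""Summary-statistic (two-sample) Mendelian randomization estimators.

Per-SNP Wald ratios are combined by multiplicative random-effects
inverse-variance weighting; MR-Egger, the weighted median and the penalized
weighted median provide pleiotropy-robust sensitivity estimates. All
estimators are sklearn-style: construct with options, ``fit`` on a harmonized
summary set (or a DataFrame with beta/se columns for both sides), read the
results off trailing-underscore attributes or ``estimate_``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._regress import wls_line
from .instruments import HarmonizedSummarySet
from .results import MREstimate

Z95 = stats.norm.ppf(0.975)

REQUIRED_COLUMNS = ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome")


def _as_table(X) -> pd.DataFrame:
    if isinstance(X, HarmonizedSummarySet):
        X = X.table
    if not isinstance(X, pd.DataFrame):
        raise TypeError("expected a HarmonizedSummarySet or DataFrame")
    missing = [c for c in REQUIRED_COLUMNS if c not in X.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    return X


def wald_ratios(h, second_order: bool = False) -> pd.DataFrame:
    """Per-variant causal estimates theta_j = beta_outcome_j / beta_exposure_j.

    The default SE is the first-order delta approximation
    se_outcome / |beta_exposure| (the NOME regime); ``second_order`` adds the
    exposure-side term. Variants with beta_exposure == 0 are dropped with a
    reason column in ``.attrs['excluded']``.
    """
    t = _as_table(h)
    keep = t["beta_exposure"] != 0
    excluded = t.loc[~keep, ["snp"] if "snp" in t.columns else []].copy()
    if "snp" in t.columns:
        excluded["reason"] = "zero_exposure_beta"
    t = t[keep]
    theta = t["beta_outcome"].to_numpy() / t["beta_exposure"].to_numpy()
    se = t["se_outcome"].to_numpy() / np.abs(t["beta_exposure"].to_numpy())
    if second_order:
        se = np.sqrt(
            se**2
            + theta**2
            * t["se_exposure"].to_numpy() ** 2
            / t["beta_exposure"].to_numpy() ** 2
        )
    out = pd.DataFrame(
        {
            "snp": t["snp"].to_numpy() if "snp" in t.columns else np.arange(len(t)),
            "theta": theta,
            "se_theta": se,
            "weight": 1.0 / se**2,
        }
    )
    out.attrs["excluded"] = excluded
    return out


def _ivw_core(theta: np.ndarray, weight: np.ndarray) -> tuple[float, float, float, int]:
    """Pooled estimate, multiplicative random-effects SE, Q and df.

    Accepts k >= 1 (a single ratio degenerates to itself with its own SE).
    """
    k = theta.size
    sw = weight.sum()
    est = float((weight * theta).sum() / sw)
    q = float((weight * (theta - est) ** 2).sum())
    se_fixed = np.sqrt(1.0 / sw)
    phi = max(1.0, np.sqrt(q / (k - 1))) if k > 1 else 1.0
    return est, float(se_fixed * phi), q, k - 1


class IVW(BaseEstimator):
    """Random-effects inverse-variance-weighted meta-analysis of Wald ratios.

    The multiplicative random-effects model inflates the fixed-effect SE by
    sqrt(Q / (k-1)), floored at 1, so heterogeneity widens but never narrows
    the interval. P-values are normal-theory.
    """

    def __init__(self, scale: str = "log-odds per SD exposure"):
        self.scale = scale

    def fit(self, X, y=None) -> "IVW":
        ratios = X if _is_ratio_table(X) else wald_ratios(X)
        if len(ratios) < 2:
            raise ValueError(
                "IVW needs >= 2 instruments; report the single Wald ratio directly"
            )
        theta = ratios["theta"].to_numpy()
        w = ratios["weight"].to_numpy()
        est, se, q, df = _ivw_core(theta, w)
        self.beta_, self.se_ = est, se
        self.ci_low_, self.ci_high_ = est - Z95 * se, est + Z95 * se
        self.p_ = float(2 * stats.norm.sf(abs(est / se)))
        self.q_, self.q_df_ = q, df
        self.q_p_ = float(stats.chi2.sf(q, df)) if df > 0 else np.nan
        self.n_instruments_ = theta.size
        return self

    @property
    def estimate_(self) -> MREstimate:
        return MREstimate(
            method="ivw",
            scale=self.scale,
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            p=self.p_,
            n_instruments=self.n_instruments_,
            q=self.q_,
            q_df=self.q_df_,
            q_p=self.q_p_,
        )


class MREgger(BaseEstimator):
    """Weighted regression of outcome on exposure associations with intercept.

    The slope is the causal estimate; the intercept estimates the average
    directional pleiotropic effect and its test is the directional-pleiotropy
    diagnostic. Valid under InSIDE with negligible measurement error in the
    SNP-exposure associations. SEs carry the multiplicative overdispersion
    scaling max(1, sqrt(Q_egger / (k-2))).
    """

    def __init__(self, scale: str = "log-odds per SD exposure", t_dist: bool = False):
        self.scale = scale
        self.t_dist = t_dist

    def fit(self, X, y=None) -> "MREgger":
        t = _as_table(X)
        if len(t) < 3:
            raise ValueError("MR-Egger needs >= 3 instruments")
        if (t["beta_exposure"] < 0).any():
            raise ValueError("MR-Egger requires exposure-raising orientation")
        bx = t["beta_exposure"].to_numpy()
        by = t["beta_outcome"].to_numpy()
        w = 1.0 / t["se_outcome"].to_numpy() ** 2
        k = bx.size
        intercept, slope, cov = wls_line(bx, by, w)
        resid = by - intercept - slope * bx
        q = float((w * resid**2).sum())
        phi = max(1.0, np.sqrt(q / (k - 2)))
        se_int = float(np.sqrt(cov[0, 0]) * phi)
        se_slope = float(np.sqrt(cov[1, 1]) * phi)
        if self.t_dist:
            pfun = lambda z: 2 * stats.t.sf(abs(z), k - 2)  # noqa: E731
            crit = stats.t.ppf(0.975, k - 2)
        else:
            pfun = lambda z: 2 * stats.norm.sf(abs(z))  # noqa: E731
            crit = Z95
        self.beta_, self.se_ = slope, se_slope
        self.ci_low_, self.ci_high_ = slope - crit * se_slope, slope + crit * se_slope
        self.p_ = float(pfun(slope / se_slope))
        self.intercept_, self.intercept_se_ = intercept, se_int
        self.intercept_p_ = float(pfun(intercept / se_int))
        self.q_, self.q_df_ = q, k - 2
        self.q_p_ = float(stats.chi2.sf(q, k - 2))
        self.n_instruments_ = k
        return self

    @property
    def estimate_(self) -> MREstimate:
        return MREstimate(
            method="egger",
            scale=self.scale,
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            p=self.p_,
            n_instruments=self.n_instruments_,
            q=self.q_,
            q_df=self.q_df_,
            q_p=self.q_p_,
            egger_intercept=self.intercept_,
            egger_intercept_se=self.intercept_se_,
            egger_intercept_p=self.intercept_p_,
        )


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of theta under weights w."""
    order = np.argsort(theta, kind="stable")
    theta = theta[order]
    p = w[order] / w.sum()
    s = np.cumsum(p) - 0.5 * p
    return float(np.interp(0.5, s, theta))


def _penalize(theta: np.ndarray, w: np.ndarray, penalty: float) -> np.ndarray:
    wm = _weighted_median(theta, w)
    q_j = w * (theta - wm) ** 2
    p_j = stats.chi2.sf(q_j, 1)
    return w * np.minimum(1.0, penalty * p_j)


class WeightedMedian(BaseEstimator):
    """Weighted-median MR estimator with parametric-bootstrap SE.

    Consistent when valid instruments carry at least half the analysis
    weight. ``penalized=True`` additionally downweights variants whose
    Cochran's Q contribution flags them as heterogeneous (penalty factor
    min(1, penalty * p_j) with p_j the upper chi2_1 tail of the contribution).
    """

    def __init__(
        self,
        penalized: bool = False,
        penalty: float = 20.0,
        n_boot: int = 1000,
        seed: int = 0,
        scale: str = "log-odds per SD exposure",
    ):
        self.penalized = penalized
        self.penalty = penalty
        self.n_boot = n_boot
        self.seed = seed
        self.scale = scale

    def fit(self, X, y=None) -> "WeightedMedian":
        import warnings as _warnings

        t = _as_table(X)
        if len(t) < 2:
            raise ValueError("weighted median needs >= 2 instruments")
        if self.n_boot < 100:
            _warnings.warn("n_boot < 100 gives unstable bootstrap SEs")
        bx = t["beta_exposure"].to_numpy()
        by = t["beta_outcome"].to_numpy()
        sx = t["se_exposure"].to_numpy()
        sy = t["se_outcome"].to_numpy()
        self.beta_ = self._point(bx, by, sy)
        rng = np.random.default_rng(self.seed)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bxb = bx + sx * rng.standard_normal(bx.size)
            byb = by + sy * rng.standard_normal(by.size)
            boots[b] = self._point(bxb, byb, sy)
        self.se_ = float(boots.std(ddof=1))
        self.ci_low_ = self.beta_ - Z95 * self.se_
        self.ci_high_ = self.beta_ + Z95 * self.se_
        self.p_ = float(2 * stats.norm.sf(abs(self.beta_ / self.se_)))
        self.n_instruments_ = bx.size
        return self

    def _point(self, bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> float:
        keep = bx != 0
        bx, by, sy = bx[keep], by[keep], sy[keep]
        theta = by / bx
        w = (bx / sy) ** 2
        if self.penalized:
            w = _penalize(theta, w, self.penalty)
        return _weighted_median(theta, w)

    @property
    def estimate_(self) -> MREstimate:
        return MREstimate(
            method="penalized_weighted_median" if self.penalized else "weighted_median",
            scale=self.scale,
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            p=self.p_,
            n_instruments=self.n_instruments_,
        )


def _is_ratio_table(X) -> bool:
    return isinstance(X, pd.DataFrame) and {"theta", "weight"} <= set(X.columns)


# ---------------------------------------------------------------------------
# thin functional wrappers


def ivw(ratios_or_harmonized, scale: str = "log-odds per SD exposure") -> MREstimate:
    return IVW(scale=scale).fit(ratios_or_harmonized).estimate_


def egger(harmonized, scale: str = "log-odds per SD exposure", t_dist: bool = False) -> MREstimate:
    return MREgger(scale=scale, t_dist=t_dist).fit(harmonized).estimate_


def weighted_median(
    harmonized, n_boot: int = 1000, seed: int = 0, scale: str = "log-odds per SD exposure"
) -> MREstimate:
    return WeightedMedian(n_boot=n_boot, seed=seed, scale=scale).fit(harmonized).estimate_


def penalized_weighted_median(
    harmonized,
    n_boot: int = 1000,
    seed: int = 0,
    penalty: float = 20.0,
    scale: str = "log-odds per SD exposure",
) -> MREstimate:
    return (
        WeightedMedian(penalized=True, penalty=penalty, n_boot=n_boot, seed=seed, scale=scale)
        .fit(harmonized)
        .estimate_
    )


def single_wald_ratio(harmonized, scale: str = "log-odds per SD exposure") -> MREstimate:
    """Causal estimate from a single instrument (the k=1 degenerate case)."""
    ratios = harmonized if _is_ratio_table(harmonized) else wald_ratios(harmonized)
    if len(ratios) != 1:
        raise ValueError("single_wald_ratio expects exactly one instrument")
    est, se, _, _ = _ivw_core(ratios["theta"].to_numpy(), ratios["weight"].to_numpy())
    return MREstimate(
        method="wald_ratio",
        scale=scale,
        beta=est,
        se=se,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        p=float(2 * stats.norm.sf(abs(est / se))),
        n_instruments=1,
    )
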