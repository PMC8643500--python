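"""Stratified non-linear Mendelian randomization.

The exposure is residualized on the genetic risk score ("IV-free" exposure,
the non-genetic component), the sample is cut into equal-count strata of that
residual (deciles by default), and a local average causal effect (LACE) — the
ratio of the IV-outcome to the IV-exposure association — is estimated within
each stratum. The LACEs are chained into a continuity-constrained
piecewise-linear causal curve with bootstrap confidence bands, and two tests
probe non-linearity: Cochran's Q over the LACEs and a quadratic test that
meta-regresses the LACEs on the stratum mean exposure.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from ._regress import (
    gwas_logistic,
    paired_simple_logistic,
    paired_simple_ols,
    simple_ols,
    wls_line,
)
from .results import LACEStratum, PiecewiseCurve, QuadraticTest, TestResult

Z95 = stats.norm.ppf(0.975)


def iv_free_exposure(exposure: np.ndarray, grs: np.ndarray) -> np.ndarray:
    """Residual of exposure on the instrument, re-centred at the exposure mean.

    Assumes a linear IV-exposure effect. Adding back the overall mean keeps
    stratum boundaries interpretable on the raw exposure scale.
    """
    exposure = np.asarray(exposure, dtype=float)
    grs = np.asarray(grs, dtype=float)
    if grs.std() == 0:
        raise ValueError("zero-variance instrument")
    slope, _ = simple_ols(grs, exposure)
    resid = exposure - exposure.mean() - slope * (grs - grs.mean())
    return resid + exposure.mean()


def stratify(residuals: np.ndarray, n_strata: int = 10) -> np.ndarray:
    """Equal-count quantile strata of the IV-free exposure (0-based labels).

    Ties are broken by stable rank so assignment is deterministic.
    """
    if n_strata < 2:
        raise ValueError("n_strata must be >= 2")
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.size
    order = np.argsort(residuals, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_strata) // n


def lace_per_stratum(
    grs: np.ndarray,
    exposure: np.ndarray,
    outcome: np.ndarray,
    strata: np.ndarray,
    outcome_kind: str = "continuous",
    iv_free: np.ndarray | None = None,
    min_n: int = 30,
    min_cases: int = 10,
) -> list[LACEStratum]:
    """Per-stratum LACE: (outcome-on-IV slope) / (exposure-on-IV slope).

    ``exposure`` sets the units of the LACE denominator (pass the raw-scale
    exposure for effects per kg/m^2-like unit). Binary outcomes use a
    within-stratum logistic regression, so the LACE is on the log-odds scale.
    Under-sized strata, strata with too few cases and strata where the
    IV-exposure slope is indistinguishable from zero are flagged and their
    LACE withheld (NaN).
    """
    grs = np.asarray(grs, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    strata = np.asarray(strata)
    if iv_free is None:
        iv_free = exposure
    out: list[LACEStratum] = []
    for s in range(int(strata.max()) + 1):
        idx = np.flatnonzero(strata == s)
        g, x, y = grs[idx], exposure[idx], outcome[idx]
        flags = []
        if idx.size < min_n:
            flags.append(f"n={idx.size}<{min_n}")
        n_cases = None
        bx, sx = simple_ols(g, x)
        by = sy = lace = se_lace = np.nan
        if outcome_kind == "binary":
            n_cases = int(np.nansum(y))
            if n_cases < min_cases or n_cases > idx.size - min_cases:
                flags.append(f"cases={n_cases}<{min_cases}")
            else:
                by_a, sy_a = gwas_logistic(g[:, None], y)
                by, sy = float(by_a[0]), float(sy_a[0])
        else:
            by, sy = simple_ols(g, y)
        if abs(bx) < 2 * sx:
            flags.append("weak_denominator")
        if not flags and np.isfinite(by):
            lace = by / bx
            se_lace = sy / abs(bx)
        res = iv_free[idx]
        out.append(
            LACEStratum(
                index=s + 1,
                low=float(res.min()),
                high=float(res.max()),
                mean_exposure=float(x.mean()),
                n=int(idx.size),
                n_cases=n_cases,
                beta_iv_exposure=float(bx),
                se_iv_exposure=float(sx),
                beta_iv_outcome=float(by),
                se_iv_outcome=float(sy),
                lace=float(lace),
                se_lace=float(se_lace),
                flagged=bool(flags),
                flag_reason=";".join(flags),
            )
        )
    return out


def _knots_and_widths(laces: list[LACEStratum]) -> tuple[np.ndarray, np.ndarray]:
    knots = np.array([laces[0].low] + [s.high for s in laces])
    return knots, np.diff(knots)


def _curve_values(slopes: np.ndarray, widths: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(slopes * widths)])


def piecewise_curve(
    laces: list[LACEStratum],
    grs: np.ndarray,
    exposure: np.ndarray,
    outcome: np.ndarray,
    strata: np.ndarray,
    outcome_kind: str = "continuous",
    n_boot: int = 500,
    seed: int = 0,
    with_tests: bool = True,
) -> PiecewiseCurve:
    """Continuity-constrained piecewise-linear curve with bootstrap bands.

    The curve value at knot k is the running integral of the segment LACEs,
    referenced to 0 at the first knot. Pointwise percentile intervals come
    from resampling individuals within strata (stratum sizes preserved).
    """
    flagged = [s.index for s in laces if s.flagged]
    if flagged:
        raise ValueError(f"flagged strata break the curve: {flagged}")
    if len(laces) < 2:
        raise ValueError("need >= 2 strata")
    knots, widths = _knots_and_widths(laces)
    slopes = np.array([s.lace for s in laces])
    values = _curve_values(slopes, widths)

    grs = np.asarray(grs, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    rng = np.random.default_rng(seed)
    boot_slopes = np.empty((n_boot, len(laces)))
    for j, stratum in enumerate(laces):
        idx = np.flatnonzero(np.asarray(strata) == stratum.index - 1)
        n_s = idx.size
        chunk = max(1, int(2_000_000 // max(n_s, 1)))
        done = 0
        while done < n_boot:
            b = min(chunk, n_boot - done)
            take = idx[rng.integers(0, n_s, size=(b, n_s))]
            Gb, Xb, Yb = grs[take], exposure[take], outcome[take]
            bx, _ = paired_simple_ols(Gb, Xb)
            if outcome_kind == "binary":
                by, _ = paired_simple_logistic(Gb, Yb)
            else:
                by, _ = paired_simple_ols(Gb, Yb)
            boot_slopes[done : done + b, j] = by / bx
            done += b
    boot_values = np.concatenate(
        [np.zeros((n_boot, 1)), np.cumsum(boot_slopes * widths[None, :], axis=1)],
        axis=1,
    )
    ok = np.all(np.isfinite(boot_values), axis=1)
    lo = np.nanpercentile(boot_values[ok], 2.5, axis=0)
    hi = np.nanpercentile(boot_values[ok], 97.5, axis=0)

    q_test = quad_test = None
    if with_tests and len(laces) >= 3:
        q_test, quad_test = nonlinearity_tests(laces)
    return PiecewiseCurve(
        knots=knots.tolist(),
        slopes=slopes.tolist(),
        values=values.tolist(),
        ci_low=lo.tolist(),
        ci_high=hi.tolist(),
        n_boot=n_boot,
        q_test=q_test,
        quadratic_test=quad_test,
    )


def nonlinearity_tests(laces: list[LACEStratum]) -> tuple[TestResult, QuadraticTest]:
    """Cochran's Q over the LACEs and the quadratic meta-regression test.

    Q compares each stratum LACE to their inverse-variance-weighted mean
    (chi-square, S-1 df). The quadratic test regresses the LACEs on stratum
    mean exposure with inverse-variance weights; a nonzero slope indicates the
    local effect changes along the exposure range, i.e. non-linearity.
    """
    usable = [s for s in laces if not s.flagged]
    if len(usable) < 3:
        raise ValueError("need >= 3 unflagged strata")
    lace = np.array([s.lace for s in usable])
    w = 1.0 / np.array([s.se_lace for s in usable]) ** 2
    pooled = (w * lace).sum() / w.sum()
    q = float((w * (lace - pooled) ** 2).sum())
    df = len(usable) - 1
    q_test = TestResult(q, df, float(stats.chi2.sf(q, df)))

    xbar = np.array([s.mean_exposure for s in usable])
    _, slope, cov = wls_line(xbar, lace, w)
    se = float(np.sqrt(cov[1, 1]))
    quad = QuadraticTest(slope, se, float(2 * stats.norm.sf(abs(slope / se))))
    return q_test, quad


class PiecewiseLinearMR(BaseEstimator):
    """End-to-end stratified non-linear MR estimator.

    ``fit(exposure, grs, outcome)`` residualizes the exposure on the score,
    cuts deciles (by default) of the IV-free exposure, estimates per-stratum
    LACEs, chains the piecewise-linear curve with bootstrap bands, and runs
    the non-linearity tests. Fitted attributes: ``strata_``, ``laces_``,
    ``curve_``, ``q_test_``, ``quadratic_test_``.
    """

    def __init__(
        self,
        n_strata: int = 10,
        outcome_kind: str = "continuous",
        n_boot: int = 500,
        seed: int = 0,
        min_n: int = 30,
        min_cases: int = 10,
    ):
        self.n_strata = n_strata
        self.outcome_kind = outcome_kind
        self.n_boot = n_boot
        self.seed = seed
        self.min_n = min_n
        self.min_cases = min_cases

    def fit(self, exposure: np.ndarray, grs: np.ndarray, outcome: np.ndarray):
        iv_free = iv_free_exposure(exposure, grs)
        self.iv_free_ = iv_free
        self.strata_ = stratify(iv_free, self.n_strata)
        self.laces_ = lace_per_stratum(
            grs,
            exposure,
            outcome,
            self.strata_,
            outcome_kind=self.outcome_kind,
            iv_free=iv_free,
            min_n=self.min_n,
            min_cases=self.min_cases,
        )
        self.curve_ = piecewise_curve(
            self.laces_,
            grs,
            exposure,
            outcome,
            self.strata_,
            outcome_kind=self.outcome_kind,
            n_boot=self.n_boot,
            seed=self.seed,
        )
        self.q_test_ = self.curve_.q_test
        self.quadratic_test_ = self.curve_.quadratic_test
        return self
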