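"""One-sample Mendelian randomization: two-stage least squares on
individual-level data, with exclusion-based and case-subtype sensitivity runs.

Stage 1 regresses the (inverse-normalized) exposure on the genetic risk score
plus covariates; stage 2 regresses the outcome on the stage-1 fitted values
plus the same covariates (linear for continuous outcomes, logistic for
binary). For the linear-linear case the SE is recomputed from proper 2SLS
residuals (y - X beta_hat with the observed exposure); for the logistic second
stage the model-based SE is reported, with an individual-resampling bootstrap
available because uncorrected second-stage SEs understate uncertainty.
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .instruments import instrument_strength
from .results import MREstimate
from .simulate import Cohort

Z95 = stats.norm.ppf(0.975)


def _covariate_design(covariates: pd.DataFrame | None) -> np.ndarray | None:
    if covariates is None or covariates.shape[1] == 0:
        return None
    cols = []
    for c in covariates.columns:
        col = covariates[c]
        if col.dtype == object or str(col.dtype) == "category" or c == "centre":
            dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True)
            cols.append(dummies.to_numpy(dtype=float))
        else:
            cols.append(col.to_numpy(dtype=float)[:, None])
    return np.hstack(cols)


class TwoStageLeastSquares(BaseEstimator):
    """2SLS causal-effect estimator using a genetic risk score instrument.

    Parameters
    ----------
    outcome_kind : 'continuous' or 'binary'.
    se_method : 'analytic' (2SLS residual SE for the linear case, model SE
        for the logistic case) or 'bootstrap' (resample individuals).
    n_boot, seed : bootstrap controls.
    """

    def __init__(
        self,
        outcome_kind: str = "continuous",
        se_method: str = "analytic",
        n_boot: int = 1000,
        seed: int = 0,
    ):
        self.outcome_kind = outcome_kind
        self.se_method = se_method
        self.n_boot = n_boot
        self.seed = seed

    def fit(
        self,
        grs: np.ndarray,
        exposure: np.ndarray,
        outcome: np.ndarray,
        covariates: pd.DataFrame | None = None,
    ) -> "TwoStageLeastSquares":
        grs = np.asarray(grs, dtype=float)
        exposure = np.asarray(exposure, dtype=float)
        outcome = np.asarray(outcome, dtype=float)
        keep = ~np.isnan(outcome)
        grs, exposure, outcome = grs[keep], exposure[keep], outcome[keep]
        cov = _covariate_design(covariates.loc[keep] if covariates is not None else None)

        self.warnings_ = []
        r2, f, weak = instrument_strength(grs, exposure)
        self.r_squared_, self.f_statistic_ = r2, f
        if weak:
            self.warnings_.append(f"weak instrument: F = {f:.2f} < 10")

        beta, se = self._fit_once(grs, exposure, outcome, cov)
        if self.se_method == "bootstrap":
            rng = np.random.default_rng(self.seed)
            n = grs.size
            boots = np.empty(self.n_boot)
            for b in range(self.n_boot):
                idx = rng.integers(0, n, size=n)
                cb = cov[idx] if cov is not None else None
                boots[b], _ = self._fit_once(grs[idx], exposure[idx], outcome[idx], cb)
            se = float(boots.std(ddof=1))

        self.beta_, self.se_ = beta, se
        self.ci_low_, self.ci_high_ = beta - Z95 * se, beta + Z95 * se
        self.p_ = float(2 * stats.norm.sf(abs(beta / se)))
        self.n_ = outcome.size
        if self.outcome_kind == "binary":
            self.n_cases_ = int(outcome.sum())
            self.n_controls_ = int(outcome.size - self.n_cases_)
        else:
            self.n_cases_ = self.n_controls_ = None
        return self

    def _fit_once(
        self,
        grs: np.ndarray,
        exposure: np.ndarray,
        outcome: np.ndarray,
        cov: np.ndarray | None,
    ) -> tuple[float, float]:
        n = grs.size
        Z1 = np.column_stack([np.ones(n), grs] + ([cov] if cov is not None else []))
        stage1 = np.linalg.lstsq(Z1, exposure, rcond=None)[0]
        fitted = Z1 @ stage1
        X2 = np.column_stack([np.ones(n), fitted] + ([cov] if cov is not None else []))
        if self.outcome_kind == "continuous":
            beta2, *_ = np.linalg.lstsq(X2, outcome, rcond=None)
            # proper 2SLS residuals: observed exposure, not fitted values
            Xobs = X2.copy()
            Xobs[:, 1] = exposure
            resid = outcome - Xobs @ beta2
            sigma2 = resid @ resid / (n - X2.shape[1])
            xtx_inv = np.linalg.inv(X2.T @ X2)
            return float(beta2[1]), float(np.sqrt(sigma2 * xtx_inv[1, 1]))
        if self.outcome_kind == "binary":
            fit = sm.Logit(outcome, X2).fit(disp=0, maxiter=100, tol=1e-8)
            if not fit.mle_retvals.get("converged", True):
                raise RuntimeError("stage-2 logistic fit did not converge")
            return float(fit.params[1]), float(fit.bse[1])
        raise ValueError(f"unknown outcome_kind {self.outcome_kind!r}")

    @property
    def estimate_(self) -> MREstimate:
        scale = (
            "log-odds per SD exposure"
            if self.outcome_kind == "binary"
            else "SD outcome per SD exposure"
        )
        return MREstimate(
            method="tsls",
            scale=scale,
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            p=self.p_,
            n=self.n_,
            n_cases=self.n_cases_,
            n_controls=self.n_controls_,
            n_instruments=1,
            warnings=list(self.warnings_),
        )


def tsls(
    cohort: Cohort,
    grs: np.ndarray,
    outcome: str,
    covariates: tuple[str, ...] = (),
    outcome_kind: str | None = None,
    se_method: str = "analytic",
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Two-stage least squares on a cohort; thin wrapper over the estimator."""
    y = cohort.outcomes[outcome].to_numpy().astype(float)
    if outcome_kind is None:
        vals = set(np.unique(y[~np.isnan(y)]))
        outcome_kind = "binary" if vals <= {0.0, 1.0} else "continuous"
    cov = cohort.covariates[list(covariates)] if covariates else None
    est = TwoStageLeastSquares(
        outcome_kind=outcome_kind, se_method=se_method, n_boot=n_boot, seed=seed
    ).fit(grs, cohort.exposure, y, covariates=cov)
    return est.estimate_


def run_exclusion_sensitivity(
    cohort: Cohort,
    grs: np.ndarray,
    exclusion_rule,
    outcome: str,
    covariates: tuple[str, ...] = (),
    **tsls_kwargs,
) -> tuple[MREstimate, dict]:
    """Re-run the 2SLS estimator on the subset NOT matched by the rule.

    ``exclusion_rule`` is either a boolean mask over individuals or a callable
    mapping the cohort's (covariates + outcomes) frame to one. Returns the
    estimate plus retained/excluded counts.
    """
    df = pd.concat(
        [cohort.covariates.reset_index(drop=True), cohort.outcomes.reset_index(drop=True)],
        axis=1,
    )
    mask = exclusion_rule(df) if callable(exclusion_rule) else np.asarray(exclusion_rule)
    mask = np.asarray(mask, dtype=bool)
    keep = ~mask
    if keep.sum() == 0:
        raise ValueError("exclusion rule removed every individual")
    sub = Cohort(
        snp_ids=cohort.snp_ids,
        effect_allele=cohort.effect_allele,
        other_allele=cohort.other_allele,
        mafs=cohort.mafs,
        genotypes=cohort.genotypes[keep],
        exposure=cohort.exposure[keep],
        exposure_raw=cohort.exposure_raw[keep],
        confounder=cohort.confounder[keep],
        covariates=cohort.covariates.loc[keep].reset_index(drop=True),
        outcomes=cohort.outcomes.loc[keep].reset_index(drop=True),
        truth=cohort.truth,
    )
    est = tsls(sub, np.asarray(grs)[keep], outcome, covariates, **tsls_kwargs)
    counts = {"retained": int(keep.sum()), "excluded": int(mask.sum())}
    return est, counts


def recode_case_subtype(cohort: Cohort, outcome: str, case_rule) -> Cohort:
    """Split a binary outcome's cases into subtype vs remaining cases.

    Adds two derived outcomes: ``<outcome>_subtype`` (subtype cases vs the
    original controls; remaining cases set missing) and ``<outcome>_rest``
    (remaining cases vs controls; subtype cases set missing). ``case_rule``
    maps the covariates+outcomes+exposure frame to a boolean mask evaluated
    among cases.
    """
    y = cohort.outcomes[outcome].to_numpy().astype(float)
    if not set(np.unique(y[~np.isnan(y)])) <= {0.0, 1.0}:
        raise ValueError(f"{outcome!r} is not binary")
    df = pd.concat(
        [cohort.covariates.reset_index(drop=True), cohort.outcomes.reset_index(drop=True)],
        axis=1,
    )
    df["exposure"] = cohort.exposure
    df["exposure_raw"] = cohort.exposure_raw
    rule_mask = np.asarray(case_rule(df) if callable(case_rule) else case_rule, dtype=bool)
    cases = y == 1
    subtype = cases & rule_mask
    rest = cases & ~rule_mask
    if subtype.sum() == 0:
        raise ValueError("case rule selected zero cases")
    y_subtype = np.where(cases, np.nan, y)
    y_subtype[subtype] = 1.0
    y_rest = np.where(cases, np.nan, y)
    y_rest[rest] = 1.0
    out = copy.copy(cohort)
    out.outcomes = cohort.outcomes.copy()
    out.outcomes[f"{outcome}_subtype"] = y_subtype
    out.outcomes[f"{outcome}_rest"] = y_rest
    return out
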