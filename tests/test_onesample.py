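import numpy as np
import pytest

import adipomr as a
from adipomr.onesample import TwoStageLeastSquares, recode_case_subtype, run_exclusion_sensitivity
from tests.conftest import make_cohort_with_grs


def iv_ratio(g, x, y):
    """Independent oracle: single-instrument IV estimate cov(G,Y)/cov(G,X)."""
    return np.cov(g, y)[0, 1] / np.cov(g, x)[0, 1]


class TestTSLS:
    def test_equals_iv_ratio_with_single_instrument(self, cont_cohort):
        cohort, grs = cont_cohort
        y = cohort.outcomes["y"].to_numpy()
        est = TwoStageLeastSquares().fit(grs, cohort.exposure, y)
        assert est.beta_ == pytest.approx(iv_ratio(grs, cohort.exposure, y), rel=1e-10)

    def test_invariant_to_affine_rescaling_of_grs(self, cont_cohort):
        cohort, grs = cont_cohort
        y = cohort.outcomes["y"].to_numpy()
        e1 = TwoStageLeastSquares().fit(grs, cohort.exposure, y)
        e2 = TwoStageLeastSquares().fit(3.7 * grs - 2.0, cohort.exposure, y)
        assert e1.beta_ == pytest.approx(e2.beta_, rel=1e-10)
        assert e1.se_ == pytest.approx(e2.se_, rel=1e-10)

    def test_recovers_causal_effect_despite_confounding(self):
        ests, ses = [], []
        for seed in range(6):
            cohort, grs = make_cohort_with_grs(
                seed=100 + seed,
                outcome_kind="continuous",
                causal_coefficients=(0.1,),
                confounder_effect_exposure=0.4,
                confounder_effect_outcome=0.6,
            )
            e = TwoStageLeastSquares().fit(grs, cohort.exposure, cohort.outcomes["y"].to_numpy())
            ests.append(e.beta_)
            ses.append(e.se_)
        # pooled estimate consistent with the truth; observational slope is not
        pooled_se = np.sqrt(np.mean(np.array(ses) ** 2) / len(ests))
        assert abs(np.mean(ests) - 0.1) < 2.5 * pooled_se
        cohort, _ = make_cohort_with_grs(
            seed=100,
            outcome_kind="continuous",
            causal_coefficients=(0.1,),
            confounder_effect_exposure=0.4,
            confounder_effect_outcome=0.6,
        )
        obs = a.fit_observational(cohort, "y", covariates=())
        assert obs.effect > 0.25  # confounding pushes it far above 0.1

    def test_null_coverage(self):
        covered = 0
        for seed in range(40):
            cohort, grs = make_cohort_with_grs(
                seed=300 + seed,
                n_individuals=2000,
                outcome_kind="continuous",
                causal_coefficients=(0.0,),
                confounder_effect_outcome=0.0,
            )
            e = TwoStageLeastSquares().fit(grs, cohort.exposure, cohort.outcomes["y"].to_numpy())
            covered += e.ci_low_ <= 0 <= e.ci_high_
        assert covered >= 33

    def test_binary_outcome_reports_log_odds_and_counts(self, binary_cohort):
        cohort, grs = binary_cohort
        est = a.tsls(cohort, grs, "y")
        assert est.scale == "log-odds per SD exposure"
        assert est.n_cases + est.n_controls == cohort.n
        assert est.odds_ratio > 0

    def test_weak_instrument_warning(self):
        cohort, grs = make_cohort_with_grs(
            seed=55, n_individuals=2000, exposure_h2=0.001, outcome_kind="continuous"
        )
        est = a.tsls(cohort, grs, "y")
        assert any("weak instrument" in w for w in est.warnings)

    def test_sex_strata_agree_without_interaction(self, cont_cohort):
        cohort, grs = cont_cohort
        y = cohort.outcomes["y"].to_numpy()
        sex = cohort.covariates["sex"].to_numpy()
        fits = {}
        for label, mask in [("male", sex == 1), ("female", sex == 0)]:
            fits[label] = TwoStageLeastSquares().fit(grs[mask], cohort.exposure[mask], y[mask])
        diff = abs(fits["male"].beta_ - fits["female"].beta_)
        joint_se = np.hypot(fits["male"].se_, fits["female"].se_)
        assert diff < 2 * joint_se


class TestExclusionSensitivity:
    def test_empty_exclusion_identical(self, cont_cohort):
        cohort, grs = cont_cohort
        full = a.tsls(cohort, grs, "y")
        est, counts = run_exclusion_sensitivity(
            cohort, grs, lambda df: np.zeros(len(df), dtype=bool), "y"
        )
        assert counts == {"retained": cohort.n, "excluded": 0}
        assert est.beta == pytest.approx(full.beta, rel=1e-12)

    def test_excluding_everyone_rejected(self, cont_cohort):
        cohort, grs = cont_cohort
        with pytest.raises(ValueError):
            run_exclusion_sensitivity(cohort, grs, lambda df: np.ones(len(df), bool), "y")

    def test_outcome_correlated_exclusion_shifts_less_than_2se(self, binary_cohort):
        """A 'medication' flag correlated with the outcome but not genotype
        (cases flagged at random) leaves the IV estimate stable."""
        cohort, grs = binary_cohort
        full = a.tsls(cohort, grs, "y")
        rng = np.random.default_rng(9)
        y = cohort.outcomes["y"].to_numpy()
        flag = (y == 1) & (rng.random(cohort.n) < 0.3)
        est, counts = run_exclusion_sensitivity(cohort, grs, flag, "y")
        assert counts["excluded"] == int(flag.sum())
        assert abs(est.beta - full.beta) < 2 * max(est.se, full.se)


class TestCaseSubtype:
    def test_all_cases_subtype_reproduces_original(self, binary_cohort):
        cohort, _ = binary_cohort
        out = recode_case_subtype(cohort, "y", lambda df: np.ones(len(df), bool))
        y = cohort.outcomes["y"].to_numpy()
        ysub = out.outcomes["y_subtype"].to_numpy()
        assert np.array_equal(ysub[~np.isnan(ysub)], y[~np.isnan(ysub)])
        assert np.nansum(out.outcomes["y_rest"].to_numpy()) == 0

    def test_subtype_and_rest_disjoint(self, binary_cohort):
        cohort, _ = binary_cohort
        rng = np.random.default_rng(3)
        out = recode_case_subtype(cohort, "y", rng.random(cohort.n) < 0.5)
        sub = out.outcomes["y_subtype"].to_numpy() == 1
        rest = out.outcomes["y_rest"].to_numpy() == 1
        assert not np.any(sub & rest)
        y = cohort.outcomes["y"].to_numpy()
        assert np.array_equal(sub | rest, y == 1)

    def test_zero_case_rule_rejected(self, binary_cohort):
        cohort, _ = binary_cohort
        with pytest.raises(ValueError):
            recode_case_subtype(cohort, "y", np.zeros(cohort.n, bool))

    def test_exposure_dependent_subtype_amplifies_estimate(self, binary_cohort):
        """Cases in the top exposure decile (weight-gain-like subtype) show a
        stronger MR signal than the remaining cases."""
        cohort, grs = binary_cohort
        cut = np.quantile(cohort.exposure, 0.9)
        out = recode_case_subtype(cohort, "y", lambda df: df["exposure"].to_numpy() >= cut)
        sub = a.tsls(out, grs, "y_subtype")
        rest = a.tsls(out, grs, "y_rest")
        assert sub.beta > rest.beta
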