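import numpy as np
import pytest

import adipomr as a
from adipomr.nonlinear import (
    PiecewiseLinearMR,
    iv_free_exposure,
    lace_per_stratum,
    nonlinearity_tests,
    piecewise_curve,
    stratify,
)
from adipomr.results import LACEStratum
from tests.conftest import make_cohort_with_grs


class TestIVFreeExposure:
    def test_residuals_orthogonal_to_instrument(self, cont_cohort):
        cohort, grs = cont_cohort
        resid = iv_free_exposure(cohort.exposure_raw, grs)
        assert abs(np.corrcoef(resid, grs)[0, 1]) < 1e-10
        assert resid.mean() == pytest.approx(cohort.exposure_raw.mean())

    def test_variance_decomposition(self, cont_cohort):
        cohort, grs = cont_cohort
        resid = iv_free_exposure(cohort.exposure_raw, grs)
        h2 = cohort.truth["config"].exposure_h2
        ratio = resid.var() / cohort.exposure_raw.var()
        assert ratio == pytest.approx(1 - h2, abs=0.01)

    def test_zero_variance_instrument_rejected(self):
        with pytest.raises(ValueError):
            iv_free_exposure(np.arange(10.0), np.ones(10))


class TestStratify:
    def test_exact_equal_counts_when_divisible(self, rng):
        x = rng.normal(size=5000)
        s = stratify(x, 10)
        assert np.bincount(s).tolist() == [500] * 10

    def test_strata_ordered_by_value(self, rng):
        x = rng.normal(size=1000)
        s = stratify(x, 5)
        means = [x[s == k].mean() for k in range(5)]
        assert means == sorted(means)

    def test_ties_assigned_deterministically(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 2.0, 2.0])
        s1, s2 = stratify(x, 2), stratify(x, 2)
        assert np.array_equal(s1, s2)
        assert np.bincount(s1).tolist() == [3, 3]

    def test_minimum_two_strata(self):
        with pytest.raises(ValueError):
            stratify(np.arange(10.0), 1)


class TestLACE:
    def test_linear_truth_gives_constant_lace(self, cont_cohort):
        cohort, grs = cont_cohort
        theta_raw = 0.405 / cohort.truth["config"].exposure_raw_sd
        resid = iv_free_exposure(cohort.exposure_raw, grs)
        strata = stratify(resid, 10)
        laces = lace_per_stratum(
            grs, cohort.exposure_raw, cohort.outcomes["y"].to_numpy(), strata, iv_free=resid
        )
        assert len(laces) == 10
        ok = [s for s in laces if not s.flagged]
        assert len(ok) >= 9
        z = [(s.lace - theta_raw) / s.se_lace for s in ok]
        assert np.mean(np.abs(z) < 2.5) >= 0.9

    def test_ratio_identity_holds_exactly(self, cont_cohort):
        cohort, grs = cont_cohort
        resid = iv_free_exposure(cohort.exposure_raw, grs)
        strata = stratify(resid, 5)
        for s in lace_per_stratum(
            grs, cohort.exposure_raw, cohort.outcomes["y"].to_numpy(), strata, iv_free=resid
        ):
            if not s.flagged:
                assert s.lace * s.beta_iv_exposure == pytest.approx(
                    s.beta_iv_outcome, rel=1e-12
                )

    def test_single_stratum_equals_whole_sample_ratio(self, cont_cohort):
        cohort, grs = cont_cohort
        y = cohort.outcomes["y"].to_numpy()
        laces = lace_per_stratum(
            grs, cohort.exposure_raw, y, np.zeros(cohort.n, dtype=int)
        )
        oracle = (np.cov(grs, y)[0, 1] / np.cov(grs, cohort.exposure_raw)[0, 1])
        assert laces[0].lace == pytest.approx(oracle, rel=1e-10)

    def test_small_or_caseless_strata_flagged(self, rng):
        grs = rng.normal(size=100)
        x = rng.normal(size=100)
        y = np.zeros(100)
        y[:3] = 1
        strata = (np.arange(100) >= 50).astype(int)
        laces = lace_per_stratum(grs, x, y, strata, outcome_kind="binary", min_n=30)
        assert any("cases" in s.flag_reason for s in laces)
        assert all(np.isnan(s.lace) for s in laces if s.flagged)

    def test_weak_denominator_flagged(self, rng):
        grs = rng.normal(size=2000)
        x = rng.normal(size=2000)  # instrument explains nothing
        y = rng.normal(size=2000)
        laces = lace_per_stratum(grs, x, y, np.zeros(2000, dtype=int), min_n=30)
        assert laces[0].flagged and "weak_denominator" in laces[0].flag_reason


def _manual_laces(slopes, bounds):
    out = []
    for i, s in enumerate(slopes):
        out.append(
            LACEStratum(
                index=i + 1,
                low=bounds[i],
                high=bounds[i + 1],
                mean_exposure=(bounds[i] + bounds[i + 1]) / 2,
                n=1000,
                n_cases=None,
                beta_iv_exposure=1.0,
                se_iv_exposure=0.1,
                beta_iv_outcome=s,
                se_iv_outcome=0.05,
                lace=s,
                se_lace=0.05,
            )
        )
    return out


class TestPiecewiseCurve:
    def test_constant_lace_gives_straight_line(self, cont_cohort):
        cohort, grs = cont_cohort
        laces = _manual_laces([0.3] * 5, np.linspace(20, 35, 6))
        resid = iv_free_exposure(cohort.exposure_raw, grs)
        strata = stratify(resid, 5)
        curve = piecewise_curve(
            laces, grs, cohort.exposure_raw, cohort.outcomes["y"].to_numpy(), strata,
            n_boot=50, seed=0, with_tests=False,
        )
        values = np.array(curve.values)
        knots = np.array(curve.knots)
        assert np.allclose(values, 0.3 * (knots - knots[0]))

    def test_continuity_identity_at_every_knot(self, cont_cohort):
        cohort, grs = cont_cohort
        model = PiecewiseLinearMR(n_strata=10, n_boot=50, seed=2).fit(
            cohort.exposure_raw, grs, cohort.outcomes["y"].to_numpy()
        )
        c = model.curve_
        for k in range(1, len(c.knots)):
            width = c.knots[k] - c.knots[k - 1]
            assert c.values[k] == pytest.approx(
                c.values[k - 1] + c.slopes[k - 1] * width, rel=1e-12, abs=1e-12
            )

    def test_flagged_strata_break_the_chain(self, cont_cohort):
        cohort, grs = cont_cohort
        laces = _manual_laces([0.3] * 3, np.linspace(20, 32, 4))
        laces[1].flagged = True
        with pytest.raises(ValueError, match="2"):
            piecewise_curve(
                laces, grs, cohort.exposure_raw, cohort.outcomes["y"].to_numpy(),
                stratify(iv_free_exposure(cohort.exposure_raw, grs), 3),
            )

    def test_curve_invariant_to_exposure_shift(self, cont_cohort):
        cohort, grs = cont_cohort
        y = cohort.outcomes["y"].to_numpy()
        m1 = PiecewiseLinearMR(n_strata=5, n_boot=30, seed=3).fit(cohort.exposure_raw, grs, y)
        m2 = PiecewiseLinearMR(n_strata=5, n_boot=30, seed=3).fit(cohort.exposure_raw + 5.0, grs, y)
        assert np.allclose(m1.curve_.slopes, m2.curve_.slopes)
        assert np.allclose(np.array(m2.curve_.knots) - 5.0, m1.curve_.knots)
        assert np.allclose(m1.curve_.values, m2.curve_.values)


class TestNonlinearityTests:
    def test_identical_laces_give_zero_q(self):
        laces = _manual_laces([0.3] * 4, np.linspace(20, 32, 5))
        q, quad = nonlinearity_tests(laces)
        assert q.statistic == pytest.approx(0.0, abs=1e-12)
        assert quad.slope == pytest.approx(0.0, abs=1e-12)

    def test_requires_three_strata(self):
        with pytest.raises(ValueError):
            nonlinearity_tests(_manual_laces([0.1, 0.2], [20, 25, 30]))

    def test_quadratic_truth_detected_and_lace_monotone(self):
        cohort, grs = make_cohort_with_grs(
            seed=91,
            outcome_kind="continuous",
            causal_function="quadratic",
            causal_coefficients=(0.0, 0.3),
        )
        model = PiecewiseLinearMR(n_strata=10, n_boot=30, seed=4).fit(
            cohort.exposure_raw, grs, cohort.outcomes["y"].to_numpy()
        )
        assert model.quadratic_test_.p < 0.01
        assert model.quadratic_test_.slope > 0
        laces = np.array([s.lace for s in model.laces_])
        means = np.array([s.mean_exposure for s in model.laces_])
        # strong upward trend of local slopes along the exposure range
        assert np.corrcoef(means, laces)[0, 1] > 0.8
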