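import numpy as np
import pytest

import adipomr as a


def make_cohort_with_grs(**cfg_kwargs):
    outcome = cfg_kwargs.pop("outcome_name", "y")
    cfg = a.SimulationConfig.small(**cfg_kwargs)
    cohort = a.simulate_cohort(cfg, outcome)
    grs, _ = a.build_grs(
        cohort.genotypes,
        cohort.snp_ids,
        cohort.effect_allele,
        cohort.other_allele,
        a.discovery_weights(cohort),
    )
    return cohort, grs


@pytest.fixture(scope="session")
def cont_cohort():
    """Continuous-outcome cohort with a moderate linear causal effect."""
    return make_cohort_with_grs(
        seed=11, outcome_kind="continuous", causal_coefficients=(0.405,)
    )


@pytest.fixture(scope="session")
def binary_cohort():
    """Rare binary-outcome cohort (depression-like prevalence)."""
    return make_cohort_with_grs(seed=12, outcome_kind="binary")


@pytest.fixture(scope="session")
def harmonized(cont_cohort):
    cohort, _ = cont_cohort
    ss = a.cohort_to_summary_stats(cohort, "y", split=0.5)
    return a.harmonize(ss.exposure_table(), ss.outcome_table())


@pytest.fixture
def rng():
    return np.random.default_rng(0)
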