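"""Synthetic cohort and summary-statistic generator.

Generates individual-level data with the statistical structure a Mendelian
randomization analysis of adiposity and mental health assumes: independent
biallelic SNP dosages under Hardy-Weinberg, an exposure whose genetic score
explains a configurable fraction of variance (default 1.6%, the variance a
72-SNP BMI instrument explains in a large biobank), a normal confounder acting
on both exposure and outcome, optional horizontal pleiotropy in several
flavours, and continuous or rare binary outcomes with a logistic liability
link. Everything is seeded and reproducible, so downstream estimators can be
validated by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from ._regress import gwas_linear, gwas_logistic
from .config import SimulationConfig

BASES = np.array(list("ACGT"))

SUMMARY_COLUMNS = ["SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]


# ---------------------------------------------------------------------------
# cohort containers


@dataclass
class Cohort:
    """Individual-level synthetic data plus the generating truth."""

    snp_ids: list[str]
    effect_allele: np.ndarray
    other_allele: np.ndarray
    mafs: np.ndarray
    genotypes: np.ndarray  # n x M dosages in [0, 2]
    exposure: np.ndarray  # standardized (SD) scale
    exposure_raw: np.ndarray  # BMI-like kg/m^2 scale
    confounder: np.ndarray
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    truth: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.genotypes, columns=self.snp_ids)
        df["exposure"] = self.exposure
        df["exposure_raw"] = self.exposure_raw
        for c in self.covariates.columns:
            df[c] = self.covariates[c].to_numpy()
        for c in self.outcomes.columns:
            df[c] = self.outcomes[c].to_numpy()
        return df

    def write(self, prefix: str | Path) -> None:
        """Write the cohort as TSV with a JSON truth sidecar."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(
            prefix.with_suffix(".tsv"), sep="\t", index=False, float_format="%.8g"
        )
        truth = dict(self.truth)
        truth["config"] = truth["config"].to_dict()
        for k in ("gamma", "alpha"):
            if k in truth and isinstance(truth[k], np.ndarray):
                truth[k] = truth[k].tolist()
        truth["snp_ids"] = self.snp_ids
        truth["effect_allele"] = self.effect_allele.tolist()
        truth["other_allele"] = self.other_allele.tolist()
        truth["mafs"] = self.mafs.tolist()
        prefix.with_suffix(".truth.json").write_text(json.dumps(truth, indent=1))


@dataclass
class SummaryStats:
    """Per-variant exposure and outcome associations from split samples."""

    table: pd.DataFrame  # snp, ea, oa, eaf, beta/se/p/n for both sides

    def exposure_table(self) -> pd.DataFrame:
        t = self.table
        return pd.DataFrame(
            {
                "SNP": t["snp"],
                "EA": t["ea"],
                "OA": t["oa"],
                "EAF": t["eaf_exposure"],
                "BETA": t["beta_exposure"],
                "SE": t["se_exposure"],
                "P": t["p_exposure"],
                "N": t["n_exposure"],
            }
        )

    def outcome_table(self) -> pd.DataFrame:
        t = self.table
        return pd.DataFrame(
            {
                "SNP": t["snp"],
                "EA": t["ea"],
                "OA": t["oa"],
                "EAF": t["eaf_outcome"],
                "BETA": t["beta_outcome"],
                "SE": t["se_outcome"],
                "P": t["p_outcome"],
                "N": t["n_outcome"],
            }
        )

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.exposure_table().to_csv(
            Path(f"{prefix}.exposure.tsv"), sep="\t", index=False, float_format="%.8g"
        )
        self.outcome_table().to_csv(
            Path(f"{prefix}.outcome.tsv"), sep="\t", index=False, float_format="%.8g"
        )


# ---------------------------------------------------------------------------
# generative steps


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw an n x M dosage matrix under Hardy-Weinberg, SNPs independent.

    Returns ``(genotypes, mafs)``; per-SNP minor-allele frequencies are drawn
    uniformly from ``config.maf_range``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=config.n_snps)
    G = rng.binomial(2, mafs[None, :], size=(config.n_individuals, config.n_snps))
    return G.astype(np.float64), mafs


def _scaled_gamma(
    config: SimulationConfig, mafs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-allele SNP-exposure effects scaled so the score explains h2."""
    if config.exposure_h2 == 0:
        return np.zeros(config.n_snps)
    raw = rng.uniform(0.2, 1.0, size=config.n_snps)  # exposure-raising alleles
    var_g = 2 * mafs * (1 - mafs)
    score_var = np.sum(raw**2 * var_g)
    return raw * np.sqrt(config.exposure_h2 / score_var)


def simulate_exposure(
    genotypes: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    mafs: np.ndarray | None = None,
    gamma: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exposure X = sum_j gamma_j g_ij + a U_i + eps_i on the SD scale.

    gamma is scaled so the genetic score contributes ``exposure_h2`` of unit
    total variance; the confounder U is standard normal. Returns
    ``(exposure, confounder, gamma)``. The exposure is mean-centred; its
    theoretical variance is 1.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n, m = genotypes.shape
    if mafs is None:
        mafs = genotypes.mean(axis=0) / 2.0
    if gamma is None:
        gamma = _scaled_gamma(config, mafs, rng)
    a = config.confounder_effect_exposure
    resid_var = 1.0 - config.exposure_h2 - a**2
    if resid_var <= 0:
        raise ValueError("exposure_h2 + confounder_effect_exposure^2 must be < 1")
    confounder = rng.standard_normal(n)
    x = genotypes @ gamma + a * confounder + np.sqrt(resid_var) * rng.standard_normal(n)
    x -= x.mean()
    return x, confounder, gamma


def _causal_value(x: np.ndarray, config: SimulationConfig) -> np.ndarray:
    c = config.causal_coefficients
    if config.causal_function == "linear":
        return c[0] * x
    if config.causal_function == "quadratic":
        theta1 = c[0]
        theta2 = c[1] if len(c) > 1 else 0.0
        return theta1 * x + theta2 * x**2
    if config.causal_function == "threshold":
        theta, cut = c[0], (c[1] if len(c) > 1 else 0.0)
        return theta * np.maximum(0.0, x - cut)
    raise ValueError(f"unknown causal_function {config.causal_function!r}")


def _draw_alpha(
    config: SimulationConfig, gamma: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    mode = config.pleiotropy_mode
    m = gamma.size
    if mode == "none":
        return np.zeros(m)
    if mode == "balanced":
        return rng.normal(0.0, config.pleiotropy_sd, size=m)
    if mode == "directional":
        return rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=m)
    if mode == "inside_violating":
        # direct effects correlated with instrument strength (InSIDE broken)
        return config.inside_rho * gamma + rng.normal(
            config.pleiotropy_mean, config.pleiotropy_sd, size=m
        )
    raise ValueError(f"unknown pleiotropy_mode {mode!r}")


def _solve_liability_intercept(
    eta: np.ndarray, prevalence: float, tol: float = 1e-4
) -> float:
    """Bisection for c0 with mean(logistic(c0 + eta)) = prevalence."""
    lo, hi = -30.0, 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        mean_p = expit(mid + eta).mean()
        if abs(mean_p - prevalence) < tol:
            return mid
        if mean_p > prevalence:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def simulate_outcome(
    exposure: np.ndarray,
    genotypes: np.ndarray,
    confounder: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    gamma: np.ndarray | None = None,
    sex: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Latent eta = f(x) + b U + sum_j alpha_j g_ij + eps.

    Continuous outcomes return eta itself; binary outcomes are Bernoulli
    draws from logistic(c0 + eta), the intercept c0 solved by bisection so
    the mean prevalence matches ``config.binary_prevalence``.
    Returns ``(outcome, alpha, c0)``.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    if gamma is None:
        gamma = np.zeros(genotypes.shape[1])
    alpha = _draw_alpha(config, gamma, rng)
    f = _causal_value(exposure, config)
    if config.sex_effect is not None and sex is not None:
        f = f * (1.0 + config.sex_effect * sex)
    eta = f + config.confounder_effect_outcome * confounder + genotypes @ alpha
    if config.outcome_kind == "continuous":
        y = eta + rng.standard_normal(exposure.size)
        return y, alpha, None
    c0 = _solve_liability_intercept(eta, config.binary_prevalence)
    p = expit(c0 + eta)
    y = rng.binomial(1, p).astype(np.float64)
    return y, alpha, c0


def _simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Baseline covariates, independent of genotype by construction."""
    return pd.DataFrame(
        {
            "age": rng.normal(57.0, 8.0, size=n),
            "sex": rng.binomial(1, 0.436, size=n),  # 1 = male
            "centre": rng.integers(0, 22, size=n),
            "tdi": rng.normal(-1.3, 3.0, size=n),
            "smoking": rng.choice(
                np.array(["never", "former", "current"]), size=n, p=[0.55, 0.34, 0.11]
            ),
        }
    )


def _assign_alleles(
    n_snps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    ea_idx = rng.integers(0, 4, size=n_snps)
    shift = rng.integers(1, 4, size=n_snps)
    oa_idx = (ea_idx + shift) % 4
    return BASES[ea_idx], BASES[oa_idx]


def simulate_cohort(
    config: SimulationConfig, outcome_name: str = "outcome"
) -> Cohort:
    """Full generative pass: genotypes, exposure, covariates, one outcome."""
    rng = np.random.default_rng(config.seed)
    G, mafs = simulate_genotypes(config, rng)
    x, u, gamma = simulate_exposure(G, config, rng, mafs=mafs)
    covariates = _simulate_covariates(config.n_individuals, rng)
    sex = covariates["sex"].to_numpy().astype(float)
    y, alpha, c0 = simulate_outcome(x, G, u, config, rng, gamma=gamma, sex=sex)
    ea, oa = _assign_alleles(config.n_snps, rng)
    snp_ids = [f"rs{i + 1:05d}" for i in range(config.n_snps)]
    exposure_raw = config.exposure_raw_mean + config.exposure_raw_sd * x
    return Cohort(
        snp_ids=snp_ids,
        effect_allele=ea,
        other_allele=oa,
        mafs=mafs,
        genotypes=G,
        exposure=x,
        exposure_raw=exposure_raw,
        confounder=u,
        covariates=covariates,
        outcomes=pd.DataFrame({outcome_name: y}),
        truth={"config": config, "gamma": gamma, "alpha": alpha, "c0": c0},
    )


# ---------------------------------------------------------------------------
# summary statistics


def cohort_to_summary_stats(
    cohort: Cohort,
    outcome_name: str,
    split: float = 0.5,
    rng: np.random.Generator | None = None,
) -> SummaryStats:
    """Two-sample GWAS summary statistics from disjoint cohort halves.

    Individuals are randomly partitioned; per-SNP exposure associations come
    from subset 1 (linear regression) and outcome associations from subset 2
    (linear for continuous outcomes, logistic for binary). Effect alleles are
    the simulated dosage-counted alleles throughout.
    """
    if not 0 < split < 1:
        raise ValueError(f"split must be in (0, 1), got {split}")
    rng = (
        np.random.default_rng(cohort.truth["config"].seed + 7)
        if rng is None
        else rng
    )
    y = cohort.outcomes[outcome_name].to_numpy().astype(float)
    mask = ~np.isnan(y)
    idx = np.flatnonzero(mask)
    perm = rng.permutation(idx)
    n1 = int(round(split * idx.size))
    if n1 < 10 or idx.size - n1 < 10:
        raise ValueError("split leaves too few individuals in a subset")
    s1, s2 = perm[:n1], perm[n1:]

    from scipy import stats as sps

    G1, G2 = cohort.genotypes[s1], cohort.genotypes[s2]
    bx, sx = gwas_linear(G1, cohort.exposure[s1])
    y2 = y[s2]
    binary = set(np.unique(y2)) <= {0.0, 1.0}
    if binary:
        by, sy = gwas_logistic(G2, y2)
    else:
        by, sy = gwas_linear(G2, y2)
    px = 2 * sps.norm.sf(np.abs(bx / sx))
    py = 2 * sps.norm.sf(np.abs(by / sy))
    table = pd.DataFrame(
        {
            "snp": cohort.snp_ids,
            "ea": cohort.effect_allele,
            "oa": cohort.other_allele,
            "eaf_exposure": G1.mean(axis=0) / 2.0,
            "beta_exposure": bx,
            "se_exposure": sx,
            "p_exposure": px,
            "n_exposure": s1.size,
            "eaf_outcome": G2.mean(axis=0) / 2.0,
            "beta_outcome": by,
            "se_outcome": sy,
            "p_outcome": py,
            "n_outcome": s2.size,
        }
    )
    if (table["se_exposure"] <= 0).any() or (table["se_outcome"] <= 0).any():
        raise RuntimeError("non-positive SE in summary statistics")
    return SummaryStats(table)


def simulate_summary_stats(
    n_snps: int,
    theta: float,
    h2: float = 0.016,
    n_exposure: int = 339_224,
    n_outcome: int = 145_668,
    prevalence: float | None = None,
    pleiotropy_mode: str = "none",
    pleiotropy_sd: float = 0.0,
    pleiotropy_mean: float = 0.0,
    inside_rho: float = 0.0,
    n_invalid: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SummaryStats, dict]:
    """Summary-level instrument-set generator.

    Draws true per-allele SNP-exposure effects gamma_j (scaled to explain
    ``h2`` of exposure variance), pleiotropic direct effects alpha_j on the
    chosen subset of SNPs, and observed associations with the sampling error
    implied by the two GWAS sample sizes. The large default discovery sample
    keeps measurement error in gamma negligible (the NOME regime MR-Egger
    assumes). Returns ``(SummaryStats, truth)``.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    mafs = rng.uniform(0.05, 0.5, size=n_snps)
    var_g = 2 * mafs * (1 - mafs)
    raw = rng.uniform(0.2, 1.0, size=n_snps)
    gamma = raw * np.sqrt(h2 / np.sum(raw**2 * var_g))

    cfg = SimulationConfig.small(
        n_snps=n_snps,
        pleiotropy_mode=pleiotropy_mode,
        pleiotropy_sd=pleiotropy_sd,
        pleiotropy_mean=pleiotropy_mean,
        inside_rho=inside_rho,
    )
    alpha = _draw_alpha(cfg, gamma, rng)
    if n_invalid is not None:
        valid = rng.permutation(n_snps)[n_invalid:]
        alpha[valid] = 0.0

    se_x = 1.0 / np.sqrt(n_exposure * var_g)
    noise_scale = 1.0 if prevalence is None else prevalence * (1 - prevalence)
    se_y = 1.0 / np.sqrt(n_outcome * var_g * noise_scale)
    beta_x = gamma + se_x * rng.standard_normal(n_snps)
    Gamma = theta * gamma + alpha
    beta_y = Gamma + se_y * rng.standard_normal(n_snps)

    from scipy import stats as sps

    ea, oa = _assign_alleles(n_snps, rng)
    table = pd.DataFrame(
        {
            "snp": [f"rs{i + 1:05d}" for i in range(n_snps)],
            "ea": ea,
            "oa": oa,
            "eaf_exposure": mafs,
            "beta_exposure": beta_x,
            "se_exposure": se_x,
            "p_exposure": 2 * sps.norm.sf(np.abs(beta_x / se_x)),
            "n_exposure": n_exposure,
            "eaf_outcome": mafs,
            "beta_outcome": beta_y,
            "se_outcome": se_y,
            "p_outcome": 2 * sps.norm.sf(np.abs(beta_y / se_y)),
            "n_outcome": n_outcome,
        }
    )
    return SummaryStats(table), {"gamma": gamma, "alpha": alpha, "theta": theta}
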