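"""Configuration-driven orchestration of the full analysis matrix.

``run`` executes the study graph — simulate cohort per instrument set,
observational regressions, genetic risk score construction, one-sample 2SLS,
two-sample summary MR (IVW, Egger, weighted and penalized weighted median)
and stratified non-linear MR — for every (instrument set x outcome x stratum x
method) cell, collecting tidy results. Any cell failure is recorded as a row
with a status and reason rather than aborting the matrix. All randomness
derives from the config seed, so a rerun of the same config is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, SimulationConfig
from .instruments import build_grs, discovery_weights, harmonize, instrument_strength
from .nonlinear import PiecewiseLinearMR
from .onesample import tsls
from .phenotypes import fit_observational, inverse_normal_transform
from .results import MREstimate, format_effect
from .simulate import Cohort, cohort_to_summary_stats, simulate_cohort
from .twosample import egger, ivw, penalized_weighted_median, wald_ratios, weighted_median

RESULT_COLUMNS = [
    "instrument_set",
    "outcome",
    "stratum",
    "method",
    "status",
    "reason",
    "scale",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "p",
    "odds_ratio",
    "or_ci_low",
    "or_ci_high",
    "n",
    "n_cases",
    "n_instruments",
    "q",
    "q_df",
    "q_p",
    "egger_intercept",
    "egger_intercept_se",
    "egger_intercept_p",
    "warnings",
]


@dataclass
class ResultsBundle:
    results: pd.DataFrame
    diagnostics: pd.DataFrame
    manifest: dict
    strata_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    curve_tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        kw = dict(sep="\t", index=False, float_format="%.10g")
        self.results.to_csv(outdir / "results.tsv", **kw)
        self.diagnostics.to_csv(outdir / "diagnostics.tsv", **kw)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=1, sort_keys=True))
        for name, t in self.strata_tables.items():
            t.to_csv(outdir / f"lace_{name}.tsv", **kw)
        for name, t in self.curve_tables.items():
            t.to_csv(outdir / f"curve_{name}.tsv", **kw)


def _stratum_mask(cohort: Cohort, stratum: str) -> np.ndarray:
    sex = cohort.covariates["sex"].to_numpy()
    if stratum == "all":
        return np.ones(cohort.n, dtype=bool)
    if stratum == "male":
        return sex == 1
    if stratum == "female":
        return sex == 0
    raise ValueError(f"unknown stratum {stratum!r}")


def _estimate_row(base: dict, est: MREstimate) -> dict:
    row = dict(base)
    row.update(
        status="ok",
        reason="",
        scale=est.scale,
        beta=est.beta,
        se=est.se,
        ci_low=est.ci_low,
        ci_high=est.ci_high,
        p=est.p,
        n=est.n,
        n_cases=est.n_cases,
        n_instruments=est.n_instruments,
        q=est.q,
        q_df=est.q_df,
        q_p=est.q_p,
        egger_intercept=est.egger_intercept,
        egger_intercept_se=est.egger_intercept_se,
        egger_intercept_p=est.egger_intercept_p,
        warnings=";".join(est.warnings),
    )
    if "log-odds" in est.scale:
        row["odds_ratio"] = est.odds_ratio
        row["or_ci_low"], row["or_ci_high"] = est.or_ci
    return row


def _error_row(base: dict, exc: Exception, status: str = "error") -> dict:
    row = dict(base)
    row.update(status=status, reason=f"{type(exc).__name__}: {exc}")
    return row


def run(config: RunConfig, outdir: str | Path | None = None) -> ResultsBundle:
    """Execute the configured analysis matrix; optionally write the bundle."""
    rows: list[dict] = []
    diags: list[dict] = []
    strata_tables: dict[str, pd.DataFrame] = {}
    curve_tables: dict[str, pd.DataFrame] = {}
    seedseq = np.random.SeedSequence(config.seed)
    set_seeds = seedseq.spawn(len(config.instrument_sets))

    for iset, child in zip(config.instrument_sets, set_seeds):
        cell_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        for oi, ospec in enumerate(config.outcomes):
            sim = SimulationConfig(
                n_individuals=config.n_individuals,
                n_snps=iset.n_snps,
                exposure_h2=iset.exposure_h2,
                confounder_effect_exposure=config.confounder_effect_exposure,
                confounder_effect_outcome=config.confounder_effect_outcome,
                pleiotropy_mode=config.pleiotropy_mode,
                pleiotropy_sd=config.pleiotropy_sd,
                pleiotropy_mean=config.pleiotropy_mean,
                causal_function=ospec.causal_function,
                causal_coefficients=ospec.causal_coefficients,
                outcome_kind=ospec.kind,
                binary_prevalence=ospec.prevalence or 0.018,
                seed=cell_seed + oi,
            )
            cohort = simulate_cohort(sim, outcome_name=ospec.name)
            cohort.exposure = inverse_normal_transform(cohort.exposure)
            weights = discovery_weights(cohort)
            grs, grs_log = build_grs(
                cohort.genotypes,
                cohort.snp_ids,
                cohort.effect_allele,
                cohort.other_allele,
                weights,
            )
            r2, f, weak = instrument_strength(grs, cohort.exposure)
            diags.append(
                {
                    "instrument_set": iset.name,
                    "outcome": ospec.name,
                    "r_squared": r2,
                    "f_statistic": f,
                    "weak_instrument": weak,
                    "n": cohort.n,
                    "n_snps_excluded_from_grs": len(grs_log),
                }
            )

            summary = cohort_to_summary_stats(cohort, ospec.name, split=config.split)
            harmonized = harmonize(summary.exposure_table(), summary.outcome_table())
            scale = (
                "log-odds per SD exposure"
                if ospec.kind == "binary"
                else "SD outcome per SD exposure"
            )

            for stratum in config.strata:
                mask = _stratum_mask(cohort, stratum)
                base = {
                    "instrument_set": iset.name,
                    "outcome": ospec.name,
                    "stratum": stratum,
                }
                for method in config.methods:
                    b = dict(base, method=method)
                    try:
                        rows.append(
                            _dispatch(
                                method,
                                b,
                                config,
                                cohort,
                                grs,
                                mask,
                                ospec,
                                harmonized,
                                scale,
                                stratum,
                                cell_seed + oi,
                                strata_tables,
                                curve_tables,
                            )
                        )
                    except ValueError as exc:
                        rows.append(_error_row(b, exc, status="withheld"))
                    except Exception as exc:  # noqa: BLE001 - cell isolation
                        rows.append(_error_row(b, exc))

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if config.bonferroni:
        m = (results["status"] == "ok").sum()
        results["p_bonferroni"] = np.minimum(1.0, results["p"] * max(m, 1))
    manifest = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "seed": config.seed,
        "package_version": __version__,
        "n_cells": len(results),
    }
    bundle = ResultsBundle(results, pd.DataFrame(diags), manifest, strata_tables, curve_tables)
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def _dispatch(
    method: str,
    base: dict,
    config: RunConfig,
    cohort: Cohort,
    grs: np.ndarray,
    mask: np.ndarray,
    ospec,
    harmonized,
    scale: str,
    stratum: str,
    seed: int,
    strata_tables: dict,
    curve_tables: dict,
) -> dict:
    y = cohort.outcomes[ospec.name].to_numpy().astype(float)
    if method == "observational":
        obs = fit_observational(
            cohort, ospec.name, covariates=tuple(config.covariates), stratum=stratum
        )
        row = dict(base)
        row.update(
            status="ok",
            reason="",
            scale=obs.scale,
            beta=np.log(obs.effect) if "odds" in obs.scale else obs.effect,
            ci_low=np.log(obs.ci_low) if "odds" in obs.scale else obs.ci_low,
            ci_high=np.log(obs.ci_high) if "odds" in obs.scale else obs.ci_high,
            p=obs.p,
            n=obs.n_total,
            n_cases=obs.n_cases,
        )
        if "odds" in obs.scale:
            row["odds_ratio"] = obs.effect
            row["or_ci_low"], row["or_ci_high"] = obs.ci_low, obs.ci_high
        return row
    if method == "tsls":
        sub_cov = cohort.covariates.loc[mask].reset_index(drop=True)
        covs = tuple(c for c in config.covariates if not (stratum != "all" and c == "sex"))
        sub = Cohort(
            snp_ids=cohort.snp_ids,
            effect_allele=cohort.effect_allele,
            other_allele=cohort.other_allele,
            mafs=cohort.mafs,
            genotypes=cohort.genotypes[mask],
            exposure=cohort.exposure[mask],
            exposure_raw=cohort.exposure_raw[mask],
            confounder=cohort.confounder[mask],
            covariates=sub_cov,
            outcomes=cohort.outcomes.loc[mask].reset_index(drop=True),
            truth=cohort.truth,
        )
        est = tsls(sub, grs[mask], ospec.name, covariates=covs, outcome_kind=ospec.kind)
        return _estimate_row(base, est)
    if method in ("ivw", "egger", "weighted_median", "penalized_weighted_median"):
        if stratum != "all":
            # summary statistics are whole-sample by construction; sex-
            # stratified two-sample runs would need stratified GWAS
            raise ValueError("two-sample methods run on the full sample only")
        if method == "ivw":
            return _estimate_row(base, ivw(wald_ratios(harmonized), scale=scale))
        if method == "egger":
            return _estimate_row(base, egger(harmonized, scale=scale))
        if method == "weighted_median":
            return _estimate_row(
                base,
                weighted_median(harmonized, n_boot=config.n_boot_median, seed=seed, scale=scale),
            )
        return _estimate_row(
            base,
            penalized_weighted_median(
                harmonized, n_boot=config.n_boot_median, seed=seed, scale=scale
            ),
        )
    if method == "nonlinear":
        model = PiecewiseLinearMR(
            n_strata=config.n_strata,
            outcome_kind=ospec.kind,
            n_boot=config.n_boot_curve,
            seed=seed,
        )
        model.fit(cohort.exposure_raw[mask], grs[mask], y[mask])
        key = f"{base['instrument_set']}_{ospec.name}_{stratum}"
        strata_tables[key] = pd.DataFrame([s.to_dict() for s in model.laces_])
        c = model.curve_
        curve_tables[key] = pd.DataFrame(
            {"knot": c.knots, "value": c.values, "ci_low": c.ci_low, "ci_high": c.ci_high}
        )
        row = dict(base)
        row.update(
            status="ok",
            reason="",
            scale=f"{scale.split(' per ')[0]} per raw exposure unit",
            beta=model.quadratic_test_.slope,
            se=model.quadratic_test_.se,
            p=model.quadratic_test_.p,
            q=model.q_test_.statistic,
            q_df=model.q_test_.df,
            q_p=model.q_test_.p,
            n=int(mask.sum()),
        )
        return row
    raise ValueError(f"unknown method {method!r}")


def report(bundle_or_dir: ResultsBundle | str | Path) -> dict[str, pd.DataFrame]:
    """Wide per-outcome summary tables with formatted effect strings.

    Binary-outcome effects render as odds ratios, e.g. ``1.50 (1.15, 1.95)``;
    continuous ones as slopes. Missing cells show an em-dash, never silence.
    """
    if isinstance(bundle_or_dir, ResultsBundle):
        results = bundle_or_dir.results
    else:
        results = pd.read_csv(Path(bundle_or_dir) / "results.tsv", sep="\t")
    tables: dict[str, pd.DataFrame] = {}
    for outcome, grp in results.groupby("outcome"):
        rows = []
        for (iset, stratum), cell in grp.groupby(["instrument_set", "stratum"]):
            row = {"instrument_set": iset, "stratum": stratum}
            for method in cell["method"].unique():
                r = cell[cell["method"] == method].iloc[0]
                if r["status"] != "ok" or pd.isna(r["beta"]) or pd.isna(r["se"]):
                    row[method] = "—"
                else:
                    as_or = isinstance(r["scale"], str) and "log-odds" in r["scale"]
                    row[method] = format_effect(r["beta"], r["se"], as_or=as_or)
            rows.append(row)
        tables[outcome] = pd.DataFrame(rows)
    return tables
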