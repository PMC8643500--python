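"""Genetic risk scores, summary-statistic harmonization and instrument strength.

The conventions here mirror standard two-sample MR practice: all effects are
oriented to the exposure-raising allele, strand flips are resolved by base
complement, and palindromic variants whose allele frequency cannot settle the
strand (EAF near 0.5) are excluded with an auditable reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Cohort

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)


@dataclass
class VariantWeight:
    """External (discovery-study) per-allele effect of one instrument SNP."""

    id: str
    effect_allele: str
    other_allele: str
    weight: float  # per-allele effect on exposure, SD units
    se: float
    eaf: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight):
            raise ValueError(f"{self.id}: weight must be finite")
        if not 0 < self.eaf < 1:
            raise ValueError(f"{self.id}: eaf must be in (0, 1)")


def read_variant_weights(path: str | Path) -> list[VariantWeight]:
    df = pd.read_csv(path, sep="\t")
    return [
        VariantWeight(r.SNP, r.EA, r.OA, float(r.BETA), float(r.SE), float(r.EAF))
        for r in df.itertuples()
    ]


def write_variant_weights(weights: list[VariantWeight], path: str | Path) -> None:
    pd.DataFrame(
        {
            "SNP": [w.id for w in weights],
            "EA": [w.effect_allele for w in weights],
            "OA": [w.other_allele for w in weights],
            "EAF": [w.eaf for w in weights],
            "BETA": [w.weight for w in weights],
            "SE": [w.se for w in weights],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def discovery_weights(
    cohort: Cohort,
    discovery_n: int = 339_224,
    rng: np.random.Generator | None = None,
) -> list[VariantWeight]:
    """Stand-in for an external discovery study's effect sizes.

    Perturbs the generating truth effects by the sampling error a discovery
    GWAS of ``discovery_n`` individuals would carry, so downstream scores use
    external weights (avoiding winner's-curse/overfitting bias from internal
    re-estimation) without access to a second individual-level cohort.
    """
    rng = np.random.default_rng(cohort.truth["config"].seed + 13) if rng is None else rng
    gamma = np.asarray(cohort.truth["gamma"], dtype=float)
    var_g = 2 * cohort.mafs * (1 - cohort.mafs)
    se = 1.0 / np.sqrt(discovery_n * var_g)
    est = gamma + se * rng.standard_normal(gamma.size)
    return [
        VariantWeight(
            cohort.snp_ids[j],
            str(cohort.effect_allele[j]),
            str(cohort.other_allele[j]),
            float(est[j]),
            float(se[j]),
            float(cohort.mafs[j]),
        )
        for j in range(gamma.size)
    ]


def build_grs(
    genotypes: np.ndarray,
    snp_ids: list[str],
    effect_allele: np.ndarray,
    other_allele: np.ndarray,
    weights: list[VariantWeight],
    standardize: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Weighted allele score: score_i = sum_j w_j d_ij.

    Dosages are flipped (d -> 2 - d) where a weight's effect allele matches
    the genotype's other allele (directly or by strand complement). Variants
    whose alleles cannot be reconciled are excluded with a logged reason.
    Returns ``(score, exclusion_log)``.
    """
    col = {s: j for j, s in enumerate(snp_ids)}
    score = np.zeros(genotypes.shape[0])
    used = 0
    exclusions: list[tuple[str, str]] = []
    for w in weights:
        j = col.get(w.id)
        if j is None:
            exclusions.append((w.id, "not_in_genotypes"))
            continue
        ea, oa = str(effect_allele[j]), str(other_allele[j])
        wea, woa = w.effect_allele, w.other_allele
        comp = (_COMPLEMENT.get(wea, "?"), _COMPLEMENT.get(woa, "?"))
        if (wea, woa) == (ea, oa) or comp == (ea, oa):
            d = genotypes[:, j]
        elif (wea, woa) == (oa, ea) or comp == (oa, ea):
            d = 2.0 - genotypes[:, j]
        else:
            exclusions.append((w.id, "allele_mismatch"))
            continue
        score = score + w.weight * d
        used += 1
    if used == 0:
        raise ValueError("no usable variants: every weight was excluded")
    if standardize:
        sd = score.std()
        if sd == 0:
            raise ValueError("zero-variance genetic risk score")
        score = (score - score.mean()) / sd
    log = pd.DataFrame(exclusions, columns=["snp", "reason"])
    return score, log


@dataclass
class HarmonizedSummarySet:
    """Exposure/outcome associations aligned to the exposure-raising allele."""

    table: pd.DataFrame
    excluded: pd.DataFrame  # columns: snp, reason

    def __len__(self) -> int:
        return len(self.table)

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
                "P": np.nan,
                "N": t.get("n_exposure", np.nan),
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
                "P": np.nan,
                "N": t.get("n_outcome", np.nan),
            }
        )


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    palindromic_window: tuple[float, float] = PALINDROMIC_EAF_WINDOW,
) -> HarmonizedSummarySet:
    """Align two GWAS summary tables to the exposure-raising allele.

    Both tables use the (SNP, EA, OA, EAF, BETA, SE, [P, N]) convention.
    Steps: match variants by id; align outcome alleles to the exposure's
    (sign-flipping beta_outcome on swapped alleles, resolving strand by
    complement, using EAF to orient palindromic variants outside the
    ambiguity window); then flip both betas wherever beta_exposure < 0 so
    every retained variant's effect allele raises the exposure. Excluded
    variants are listed with reasons. The result is a normal form:
    re-harmonizing it is a no-op.
    """
    exp = exposure_stats.set_index("SNP", drop=False)
    out = outcome_stats.set_index("SNP", drop=False)
    excluded: list[tuple[str, str]] = []
    rows: list[dict] = []
    for snp in exp.index:
        if snp not in out.index:
            excluded.append((snp, "unmatched"))
            continue
        e, o = exp.loc[snp], out.loc[snp]
        ea_e, oa_e = str(e.EA), str(e.OA)
        ea_o, oa_o = str(o.EA), str(o.OA)
        beta_y, eaf_y = float(o.BETA), float(o.EAF)

        if _is_palindromic(ea_e, oa_e):
            lo, hi = palindromic_window
            if lo <= float(e.EAF) <= hi:
                excluded.append((snp, "palindromic_ambiguous"))
                continue
            if {ea_o, oa_o} != {ea_e, oa_e}:
                excluded.append((snp, "allele_mismatch"))
                continue
            if ea_o == oa_e:  # labelled as swapped
                beta_y, eaf_y = -beta_y, 1 - eaf_y
            # strand labels are uninformative for palindromes: frequencies
            # must land on the same side of 0.5 once aligned
            if (float(e.EAF) < 0.5) != (eaf_y < 0.5):
                beta_y, eaf_y = -beta_y, 1 - eaf_y
        else:
            comp_ea, comp_oa = _COMPLEMENT.get(ea_o, "?"), _COMPLEMENT.get(oa_o, "?")
            if (ea_o, oa_o) == (ea_e, oa_e) or (comp_ea, comp_oa) == (ea_e, oa_e):
                pass
            elif (ea_o, oa_o) == (oa_e, ea_e) or (comp_ea, comp_oa) == (oa_e, ea_e):
                beta_y, eaf_y = -beta_y, 1 - eaf_y
            else:
                excluded.append((snp, "allele_mismatch"))
                continue

        beta_x, eaf_x = float(e.BETA), float(e.EAF)
        ea, oa = ea_e, oa_e
        if beta_x < 0:  # orient to the exposure-raising allele
            beta_x, beta_y = -beta_x, -beta_y
            eaf_x, eaf_y = 1 - eaf_x, 1 - eaf_y
            ea, oa = oa, ea
        rows.append(
            {
                "snp": snp,
                "ea": ea,
                "oa": oa,
                "eaf_exposure": eaf_x,
                "beta_exposure": beta_x,
                "se_exposure": float(e.SE),
                "eaf_outcome": eaf_y,
                "beta_outcome": beta_y,
                "se_outcome": float(o.SE),
                "n_exposure": float(e.N) if "N" in e.index else np.nan,
                "n_outcome": float(o.N) if "N" in o.index else np.nan,
            }
        )
    for snp in out.index:
        if snp not in exp.index:
            excluded.append((snp, "unmatched"))
    table = pd.DataFrame(
        rows,
        columns=[
            "snp",
            "ea",
            "oa",
            "eaf_exposure",
            "beta_exposure",
            "se_exposure",
            "eaf_outcome",
            "beta_outcome",
            "se_outcome",
            "n_exposure",
            "n_outcome",
        ],
    )
    return HarmonizedSummarySet(table, pd.DataFrame(excluded, columns=["snp", "reason"]))


def read_vcf_dosages(
    path: str | Path, ids: set[str] | None = None
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Dosage matrix from a VCF (optional input path for real genotypes).

    Uses the FORMAT/DS field when present, otherwise hard-call genotype
    counts of the ALT allele. Multi-allelic records are skipped. Returns
    ``(dosages, snp_ids, effect_allele, other_allele)`` with the ALT allele
    as the dosage-counted (effect) allele.
    """
    from cyvcf2 import VCF

    snp_ids: list[str] = []
    ea: list[str] = []
    oa: list[str] = []
    cols: list[np.ndarray] = []
    for var in VCF(str(path)):
        if len(var.ALT) != 1:
            continue
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if ids is not None and vid not in ids:
            continue
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            lut = np.array([0.0, 1.0, np.nan, 2.0])
            d = lut[np.asarray(var.gt_types)]
        snp_ids.append(vid)
        ea.append(var.ALT[0])
        oa.append(var.REF)
        cols.append(d)
    if not cols:
        raise ValueError(f"no usable biallelic variants in {path}")
    return np.column_stack(cols), snp_ids, np.array(ea), np.array(oa)


def instrument_strength(
    grs: np.ndarray, exposure: np.ndarray, n: int | None = None
) -> tuple[float, float, bool]:
    """Variance explained and F-statistic of the score on the exposure.

    F = R^2 (n - 2) / (1 - R^2); F < 10 flags likely weak-instrument bias.
    Returns ``(r_squared, f_statistic, weak_flag)``.
    """
    grs = np.asarray(grs, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if n is None:
        n = grs.size
    if n <= 2:
        raise ValueError("need n > 2")
    if grs.std() == 0:
        raise ValueError("zero-variance score")
    r = np.corrcoef(grs, exposure)[0, 1]
    r2 = float(r**2)
    f = r2 * (n - 2) / (1 - r2)
    return r2, float(f), f < 10.0


def f_statistic(r_squared: float, n: int) -> float:
    """F from variance explained: R^2 (n-2) / (1-R^2)."""
    if n <= 2:
        raise ValueError("need n > 2")
    return r_squared * (n - 2) / (1 - r_squared)
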