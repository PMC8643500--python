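import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import adipomr as a
from adipomr.instruments import VariantWeight, build_grs, harmonize, instrument_strength

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _weights(ids, eas, oas, betas):
    return [
        VariantWeight(i, e, o, b, 0.01, 0.3) for i, e, o, b in zip(ids, eas, oas, betas)
    ]


class TestGRS:
    def test_zero_dosages_zero_score(self):
        G = np.zeros((5, 2))
        w = _weights(["rs1", "rs2"], "AC", "CG", [0.3, 0.3])
        score, log = build_grs(G, ["rs1", "rs2"], np.array(["A", "C"]), np.array(["C", "G"]), w, standardize=False)
        assert np.all(score == 0) and len(log) == 0

    def test_allele_flip_with_weight_negation_invariant(self, rng):
        G = rng.binomial(2, 0.3, size=(200, 2)).astype(float)
        ids = ["rs1", "rs2"]
        ea, oa = np.array(["A", "C"]), np.array(["C", "T"])
        w1 = _weights(ids, ["A", "C"], ["C", "T"], [0.4, -0.2])
        # flip variant 2's labels and negate its weight
        w2 = _weights(ids, ["A", "T"], ["C", "C"], [0.4, 0.2])
        s1, _ = build_grs(G, ids, ea, oa, w1, standardize=False)
        s2, _ = build_grs(G, ids, ea, oa, w2, standardize=False)
        # scores differ by a constant (2 * weight per flipped variant)
        assert np.allclose(s1 - s1.mean(), s2 - s2.mean())

    def test_unresolvable_alleles_excluded_with_reason(self, rng):
        G = rng.binomial(2, 0.3, size=(50, 2)).astype(float)
        ids = ["rs1", "rs2"]
        w = _weights(ids, ["A", "G"], ["C", "C"], [0.4, 0.2])
        _, log = build_grs(G, ids, np.array(["A", "A"]), np.array(["C", "C"]), w)
        assert log.to_dict("records") == [{"snp": "rs2", "reason": "allele_mismatch"}]

    def test_score_variance_explained_matches_h2(self, cont_cohort):
        cohort, grs = cont_cohort
        r2, f, weak = instrument_strength(grs, cohort.exposure)
        assert 0.011 <= r2 <= 0.022
        assert not weak


class TestInstrumentStrength:
    def test_study_scale_f_statistic(self):
        # R^2 = 1.6% in n = 145 668 gives a decisively strong instrument
        r2, n = 0.016, 145_668
        f = a.instruments.f_statistic(r2, n)
        assert f == pytest.approx(2368.6, abs=1.0)
        assert f > 10

    def test_weak_instrument_flagged(self):
        assert a.instruments.f_statistic(0.0, 1000) == 0.0
        assert a.instruments.f_statistic(0.0001, 50_000) == pytest.approx(5.0, abs=0.01)
        x = np.arange(100.0)
        _, _, weak = instrument_strength(np.repeat(x, 2)[:100], np.random.default_rng(0).normal(size=100))
        assert weak

    def test_zero_variance_score_rejected(self):
        with pytest.raises(ValueError):
            instrument_strength(np.ones(100), np.random.default_rng(0).normal(size=100))


def _table(snp, ea, oa, eaf, beta, se=0.01, n=1000):
    return pd.DataFrame(
        {"SNP": snp, "EA": ea, "OA": oa, "EAF": eaf, "BETA": beta, "SE": se, "P": 0.5, "N": n}
    )


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_beta(self):
        exp = _table(["rs1"], ["A"], ["C"], [0.3], [0.1])
        out = _table(["rs1"], ["C"], ["A"], [0.7], [0.2])
        h = harmonize(exp, out)
        assert len(h) == 1
        assert h.table.loc[0, "beta_outcome"] == pytest.approx(-0.2)
        assert h.table.loc[0, "eaf_outcome"] == pytest.approx(0.3)

    def test_negative_exposure_beta_reoriented(self):
        exp = _table(["rs1"], ["A"], ["C"], [0.3], [-0.1])
        out = _table(["rs1"], ["A"], ["C"], [0.3], [0.2])
        h = harmonize(exp, out)
        r = h.table.loc[0]
        assert r["beta_exposure"] == pytest.approx(0.1)
        assert r["beta_outcome"] == pytest.approx(-0.2)
        assert (r["ea"], r["oa"]) == ("C", "A")

    def test_ambiguous_palindrome_excluded(self):
        exp = _table(["rs1"], ["A"], ["T"], [0.50], [0.1])
        out = _table(["rs1"], ["A"], ["T"], [0.50], [0.2])
        h = harmonize(exp, out)
        assert len(h) == 0
        assert h.excluded.to_dict("records") == [
            {"snp": "rs1", "reason": "palindromic_ambiguous"}
        ]

    def test_unmatched_variants_excluded(self):
        exp = _table(["rs1", "rs2"], ["A", "A"], ["C", "C"], [0.3, 0.3], [0.1, 0.1])
        out = _table(["rs2"], ["A"], ["C"], [0.3], [0.2])
        h = harmonize(exp, out)
        assert set(h.table["snp"]) == {"rs2"}
        assert ("rs1", "unmatched") in h.excluded.itertuples(index=False, name=None)

    def test_strand_complement_resolved(self):
        exp = _table(["rs1"], ["A"], ["C"], [0.3], [0.1])
        out = _table(["rs1"], ["T"], ["G"], [0.3], [0.2])  # same variant, other strand
        h = harmonize(exp, out)
        assert len(h) == 1
        assert h.table.loc[0, "beta_outcome"] == pytest.approx(0.2)

    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from("ACGT"),
                st.integers(0, 3),
                st.floats(0.05, 0.95),
                st.floats(-0.5, 0.5),
                st.floats(-0.5, 0.5),
                st.booleans(),
                st.booleans(),
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_harmonize_is_idempotent_normal_form(self, data):
        """harmonize(harmonize(x)) == harmonize(x); every variant lands in
        exactly one of retained/excluded; retained exposure betas >= 0."""
        bases = "ACGT"
        rows_e, rows_o = [], []
        for i, (ea, shift, eaf, bx, by, swap, comp) in enumerate(data):
            oa = bases[(bases.index(ea) + 1 + shift % 3) % 4]
            if oa == ea:
                oa = bases[(bases.index(ea) + 1) % 4]
            rows_e.append((f"rs{i}", ea, oa, eaf, bx))
            ea_o, oa_o = (oa, ea) if swap else (ea, oa)
            eaf_o = 1 - eaf if swap else eaf
            if comp:
                ea_o, oa_o = COMP[ea_o], COMP[oa_o]
            rows_o.append((f"rs{i}", ea_o, oa_o, eaf_o, -by if swap else by))
        exp = _table(*map(list, zip(*rows_e)))
        out = _table(*map(list, zip(*rows_o)))
        h1 = harmonize(exp, out)
        assert (h1.table["beta_exposure"] >= 0).all()
        assert set(h1.table["snp"]) | set(h1.excluded["snp"]) == set(exp["SNP"])
        assert set(h1.table["snp"]) & set(h1.excluded["snp"]) == set()
        h2 = harmonize(h1.exposure_table(), h1.outcome_table())
        pd.testing.assert_frame_equal(
            h1.table.reset_index(drop=True),
            h2.table.reset_index(drop=True),
            check_exact=False,
            atol=1e-12,
        )

    def test_wald_ratio_invariant_to_simultaneous_allele_flip(self):
        exp1 = _table(["rs1"], ["A"], ["C"], [0.3], [0.1])
        out1 = _table(["rs1"], ["A"], ["C"], [0.3], [0.2])
        exp2 = _table(["rs1"], ["C"], ["A"], [0.7], [-0.1])
        out2 = _table(["rs1"], ["C"], ["A"], [0.7], [-0.2])
        r1 = a.wald_ratios(harmonize(exp1, out1))
        r2 = a.wald_ratios(harmonize(exp2, out2))
        assert r1.loc[0, "theta"] == pytest.approx(r2.loc[0, "theta"], rel=1e-12)
        assert r1.loc[0, "se_theta"] == pytest.approx(r2.loc[0, "se_theta"], rel=1e-12)


VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\trs1\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\trs2\tG\tT\t.\tPASS\t.\tGT\t0/1\t0/1\t0/0
1\t300\trs3\tA\tC,G\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0
"""


def test_vcf_dosage_ingestion(tmp_path):
    from adipomr.instruments import read_vcf_dosages

    vcf = tmp_path / "toy.vcf"
    vcf.write_text(VCF_TEXT)
    dosages, ids, ea, oa = read_vcf_dosages(vcf)
    assert ids == ["rs1", "rs2"]  # the multi-allelic rs3 is skipped
    assert ea.tolist() == ["C", "T"] and oa.tolist() == ["A", "G"]
    assert dosages.tolist() == [[0.0, 1.0], [1.0, 1.0], [2.0, 0.0]]
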