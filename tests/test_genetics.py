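"""Variant QC, the HWE exact test, polygenic scoring and standardization."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from ddpgs.genetics import (
    GenotypeMatrix,
    compute_pgs,
    filter_variants,
    hwe_exact_pvalues,
    hwe_exact_test,
    is_strand_ambiguous,
    standardize_scores,
)


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Direct log-factorial enumeration over all heterozygote counts."""
    n = n_AA + n_Aa + n_aa
    n_a = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    hets = np.arange(n_a % 2, n_a + 1, 2)
    logp = np.array(
        [
            gammaln(n + 1)
            - gammaln(n - h - (n_a - h) // 2 + 1)
            - gammaln(h + 1)
            - gammaln((n_a - h) // 2 + 1)
            + h * np.log(2)
            for h in hets
        ]
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_Aa][0]
    return min(p[p <= p_obs * (1 + 1e-12)].sum(), 1.0)


class TestHWEExactTest:
    def test_two_homozygotes_matches_enumeration(self):
        # n=2, allele count 2: het in {0, 2} with P(0)=1/3, P(2)=2/3
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3, abs=1e-12)

    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 57) == 1.0

    def test_matches_enumeration_oracle_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            n = int(rng.integers(1, 120))
            a = int(rng.integers(0, n + 1))
            b = int(rng.integers(0, n - a + 1))
            c = n - a - b
            assert hwe_exact_test(a, b, c) == pytest.approx(
                hwe_enumeration_oracle(a, b, c), abs=1e-12
            )

    def test_allele_label_symmetry(self):
        assert hwe_exact_test(30, 25, 10) == pytest.approx(
            hwe_exact_test(10, 25, 30), abs=1e-15
        )

    def test_vectorised_pvalues_agree_with_scalar(self):
        hets, pvals = hwe_exact_pvalues(n_a=17, n=40)
        for h, p in zip(hets, pvals):
            n_aa = (17 - h) // 2
            assert hwe_exact_test(40 - h - n_aa, int(h), n_aa) == pytest.approx(p, abs=1e-15)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 1)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


def _matrix(dosages, alleles):
    m = len(alleles)
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": ["1"] * m,
            "pos": np.arange(m) + 1,
            "allele1": [a[0] for a in alleles],
            "allele2": [a[1] for a in alleles],
        }
    )
    d = np.asarray(dosages, dtype=float)
    return GenotypeMatrix(
        subjects=[f"s{i}" for i in range(d.shape[0])], variants=variants, dosage=d
    )


class TestFilterVariants:
    def test_ambiguous_always_removed(self):
        assert is_strand_ambiguous("A", "T") and is_strand_ambiguous("g", "c")
        d = np.random.default_rng(0).binomial(2, 0.3, size=(50, 1)).astype(float)
        kept, counts = filter_variants(_matrix(d, [("A", "T")]))
        assert kept == [] and counts["ambiguous"] == 1

    def test_maf_threshold_is_strict(self):
        # 100 subjects, 8 alt alleles -> MAF 0.04: removed (0.04 is not > 0.05)
        d = np.zeros((100, 1))
        d[:8, 0] = 1.0
        kept, counts = filter_variants(_matrix(d, [("A", "C")]))
        assert kept == [] and counts["maf"] == 1

    def test_one_violation_per_rule_tallied(self):
        rng = np.random.default_rng(0)
        n = 200
        clean = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
        ambiguous = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        rare = np.zeros((n, 1))
        rare[:2, 0] = 1.0  # MAF 0.005
        gappy = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        gappy[: int(0.05 * n), 0] = np.nan  # 5% missing
        hwe_bad = np.ones((n, 1))  # all heterozygous: extreme HWE violation
        d = np.hstack([clean[:, :2], ambiguous, gappy, rare, hwe_bad, clean[:, 2:]])
        alleles = [("A", "C"), ("A", "G"), ("C", "G"), ("T", "C"), ("T", "G"),
                   ("A", "C"), ("A", "G")]
        kept, counts = filter_variants(_matrix(d, alleles))
        assert counts == {"ambiguous": 1, "missingness": 1, "maf": 1, "hwe": 1}
        assert kept == ["v0", "v1", "v6"]

    def test_survivors_independent_of_row_order(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.25, size=(120, 6)).astype(float)
        alleles = [("A", "C")] * 3 + [("A", "T")] + [("T", "G")] * 2
        gm = _matrix(d, alleles)
        kept1, _ = filter_variants(gm)
        perm = [3, 0, 5, 1, 4, 2]
        gm2 = GenotypeMatrix(
            subjects=gm.subjects,
            variants=gm.variants.iloc[perm],
            dosage=gm.dosage[:, perm],
        )
        kept2, _ = filter_variants(gm2)
        assert set(kept1) == set(kept2)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            filter_variants(_matrix(np.zeros((3, 0)), []))


class TestComputePGS:
    def test_zero_weights_zero_scores(self, toy_genotypes):
        w = pd.DataFrame(
            {"variant_id": ["rs1", "rs2"], "effect_allele": ["G", "T"], "weight": [0.0, 0.0]}
        )
        res = compute_pgs(toy_genotypes, w)
        assert np.allclose(res.raw.to_numpy(), 0.0)

    def test_single_snp_effect_dosage(self, toy_genotypes):
        w = pd.DataFrame({"variant_id": ["rs1"], "effect_allele": ["G"], "weight": [0.5]})
        res = compute_pgs(toy_genotypes, w)
        np.testing.assert_allclose(res.raw.to_numpy(), 0.5 * toy_genotypes.dosage[:, 0])

    def test_flip_when_effect_allele_is_ref(self, toy_genotypes):
        w = pd.DataFrame({"variant_id": ["rs1"], "effect_allele": ["A"], "weight": [1.0]})
        res = compute_pgs(toy_genotypes, w)
        np.testing.assert_allclose(res.raw.to_numpy(), 2.0 - toy_genotypes.dosage[:, 0])
        assert res.n_flipped == 1

    def test_matches_double_loop_oracle_with_flips_and_missing(self):
        rng = np.random.default_rng(9)
        n, m = 50, 20
        d = rng.binomial(2, rng.uniform(0.1, 0.5, size=m), size=(n, m)).astype(float)
        d[rng.random((n, m)) < 0.05] = np.nan
        pairs = [("A", "C"), ("T", "G"), ("G", "A"), ("C", "T")]
        alleles = [pairs[int(i)] for i in rng.integers(0, 4, size=m)]
        gm = _matrix(d, alleles)
        # half the weights point at allele1 (flip), half at allele2
        eff = [alleles[j][int(rng.integers(0, 2))] for j in range(m)]
        w = pd.DataFrame(
            {
                "variant_id": [f"v{j}" for j in range(m)],
                "effect_allele": eff,
                "weight": rng.normal(size=m),
            }
        )
        res = compute_pgs(gm, w)

        expected = np.zeros(n)
        for j in range(m):
            col = d[:, j].copy()
            if eff[j] == alleles[j][0]:
                col = 2.0 - col
            fill = np.nanmean(col)
            col = np.where(np.isnan(col), fill, col)
            for i in range(n):
                expected[i] += w["weight"][j] * col[i]
        np.testing.assert_allclose(res.raw.to_numpy(), expected, atol=1e-12)

    def test_unmatched_weights_reported(self, toy_genotypes):
        w = pd.DataFrame(
            {
                "variant_id": ["rs1", "rs_nope", "rs2"],
                "effect_allele": ["G", "A", "Z"],
                "weight": [1.0, 1.0, 1.0],
            }
        )
        res = compute_pgs(toy_genotypes, w)
        assert res.n_matched == 1
        assert set(res.unmatched) == {"rs_nope", "rs2"}

    def test_no_matches_is_an_error(self, toy_genotypes):
        w = pd.DataFrame({"variant_id": ["nope"], "effect_allele": ["A"], "weight": [1.0]})
        with pytest.raises(ValueError):
            compute_pgs(toy_genotypes, w)

    def test_allele_flip_invariance_of_zscores(self, toy_genotypes):
        """Recoding the effect allele and negating the weight shifts the raw
        score by a constant, leaving within-group z-scores unchanged."""
        w1 = pd.DataFrame({"variant_id": ["rs1"], "effect_allele": ["G"], "weight": [0.7]})
        w2 = pd.DataFrame({"variant_id": ["rs1"], "effect_allele": ["A"], "weight": [-0.7]})
        groups = pd.Series(["g"] * 5, index=pd.Index([f"s{i}" for i in range(5)], name="subject_id"))
        z1 = standardize_scores(compute_pgs(toy_genotypes, w1).raw, groups)
        z2 = standardize_scores(compute_pgs(toy_genotypes, w2).raw, groups)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)


class TestStandardize:
    def test_symmetric_triple(self):
        idx = pd.Index(["a", "b", "c"])
        z = standardize_scores(pd.Series([1.0, 2.0, 3.0], index=idx),
                               pd.Series(["g"] * 3, index=idx))
        np.testing.assert_allclose(z.to_numpy(), [-1.0, 0.0, 1.0])

    def test_groupwise_moments(self):
        rng = np.random.default_rng(4)
        idx = pd.Index([f"s{i}" for i in range(400)])
        raw = pd.Series(rng.normal(5, 3, size=400), index=idx)
        groups = pd.Series(rng.choice(["EUR", "AFR", "AMR"], size=400), index=idx)
        z = standardize_scores(raw, groups)
        for g, chunk in z.groupby(groups):
            assert abs(chunk.mean()) < 1e-9
            assert abs(chunk.std(ddof=1) - 1) < 1e-9

    def test_joint_vs_separate_differ_when_means_differ(self):
        idx = pd.Index(list("abcdef"))
        raw = pd.Series([1.0, 2, 3, 11, 12, 13], index=idx)
        two = standardize_scores(raw, pd.Series(["x"] * 3 + ["y"] * 3, index=idx))
        one = standardize_scores(raw, pd.Series(["x"] * 6, index=idx))
        assert not np.allclose(two.to_numpy(), one.to_numpy())

    def test_zero_variance_group_named_in_error(self):
        idx = pd.Index(["a", "b", "c"])
        with pytest.raises(ValueError, match="flatgrp"):
            standardize_scores(pd.Series([1.0, 1.0, 2.0], index=idx),
                               pd.Series(["flatgrp", "flatgrp", "other"], index=idx))


class TestIO:
    def test_dosage_tsv_roundtrip(self, toy_genotypes, tmp_path):
        path = tmp_path / "geno.tsv"
        toy_genotypes.to_dosage_tsv(path)
        back = GenotypeMatrix.from_dosage_tsv(path)
        assert back.subjects == toy_genotypes.subjects
        np.testing.assert_allclose(back.dosage, toy_genotypes.dosage)
        assert back.variants["variant_id"].tolist() == ["rs1", "rs2", "rs3", "rs4"]

    def test_vcf_gt_reading(self, tmp_path):
        vcf = tmp_path / "tiny.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/1\t./.\t0/0\n"
        )
        gm = GenotypeMatrix.from_vcf(vcf)
        assert gm.subjects == ["s0", "s1", "s2"]
        np.testing.assert_allclose(gm.dosage[:, 0], [0, 1, 2])
        assert gm.dosage[1, 1] != gm.dosage[1, 1]  # missing -> NaN
        np.testing.assert_allclose(gm.dosage[[0, 2], 1], [1, 0])
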