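"""Variant QC and polygenic scoring.

Variant filters (applied in order, each on the survivors of the previous):
strand-ambiguity (allele pair A/T or C/G), call missingness (< 2%), minor
allele frequency (> 5%), and Hardy–Weinberg equilibrium exact-test p-value
(> 1e-3).  The HWE test is the conditional exact test on hard genotype
counts, exact at the low counts where the chi-square approximation fails.

A polygenic score is the weighted sum of effect-allele dosages over all
matched variants; dosages are flipped (2 - d) when the weight's effect
allele is the variant's other allele, and missing dosages are mean-imputed
at twice the effect-allele frequency.  Scores are z-standardised within
each genetic ancestry group before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass
class GenotypeMatrix:
    """Dosage matrix (subjects x variants) with variant metadata.

    ``dosage`` holds effect counts of ``allele2`` in [0, 2]; NaN = missing.
    ``variants`` is a DataFrame with columns
    variant_id, chrom, pos, allele1, allele2 (variant_id unique).
    """

    subjects: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subjects), len(self.variants)):
            raise ValueError("dosage shape must be (n_subjects, n_variants)")
        if self.variants["variant_id"].duplicated().any():
            raise ValueError("variant ids must be unique")
        valid = np.isnan(self.dosage) | ((self.dosage >= 0) & (self.dosage <= 2))
        if not valid.all():
            raise ValueError("dosages must lie in [0, 2] or be missing")

    def subset(self, variant_ids) -> "GenotypeMatrix":
        idx = self.variants.set_index("variant_id").index.get_indexer(list(variant_ids))
        if (idx < 0).any():
            raise KeyError("unknown variant id in subset request")
        return GenotypeMatrix(
            subjects=list(self.subjects),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
        )

    # --- I/O -----------------------------------------------------------
    def to_dosage_tsv(self, path) -> None:
        """Wide TSV: variant_id, chrom, pos, allele1, allele2, <subject...>."""
        dos = pd.DataFrame(self.dosage.T, columns=self.subjects)
        out = pd.concat([self.variants.reset_index(drop=True), dos], axis=1)
        out.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_dosage_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        meta_cols = ["variant_id", "chrom", "pos", "allele1", "allele2"]
        subjects = [c for c in df.columns if c not in meta_cols]
        return cls(
            subjects=subjects,
            variants=df[meta_cols].copy(),
            dosage=df[subjects].to_numpy(dtype=float).T,
        )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read dosages from a VCF: DS format field if present, else GT
        hard calls (count of ALT alleles; missing genotype -> NaN)."""
        from cyvcf2 import VCF  # optional dependency

        vcf = VCF(str(path))
        subjects = list(vcf.samples)
        rows, cols = [], []
        for v in vcf:
            vid = v.ID or f"{v.CHROM}:{v.POS}"
            rows.append((vid, v.CHROM, v.POS, v.REF, v.ALT[0]))
            try:
                ds = np.asarray(v.format("DS"), dtype=float).ravel()
            except (KeyError, TypeError, ValueError):
                gt = np.asarray(v.genotype.array())[:, :2]
                ds = np.where((gt < 0).any(axis=1), np.nan, (gt > 0).sum(axis=1)).astype(float)
            cols.append(ds)
        variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "allele1", "allele2"])
        return cls(subjects=subjects, variants=variants, dosage=np.column_stack(cols))


def is_strand_ambiguous(allele1: str, allele2: str) -> bool:
    return {str(allele1).upper(), str(allele2).upper()} in AMBIGUOUS_PAIRS


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided conditional exact test of Hardy–Weinberg equilibrium.

    Given the observed allele counts, sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that
    of the observed count.  Monomorphic variants return p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_a = 2 * n_aa + n_Aa  # minor-or-not does not matter; distribution is symmetric
    hets, pvals = hwe_exact_pvalues(n_a, n)
    idx = np.flatnonzero(hets == n_Aa)
    if idx.size == 0:  # parity mismatch cannot occur for valid counts
        raise ValueError("heterozygote count incompatible with allele count")
    return float(pvals[idx[0]])


def hwe_exact_pvalues(n_a: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact HWE p-value for every possible heterozygote count at once.

    Returns (het counts, p-values) for ``n_a`` copies of one allele among
    ``2n``.  p(h) sums the probabilities of all heterozygote counts no more
    probable than h (ties included with a 1e-12 relative guard against
    floating-point asymmetry in mathematically equal tails).
    """
    probs, hets = _hwe_het_distribution(n_a, n)
    order = np.argsort(probs, kind="stable")
    csum = np.cumsum(probs[order])
    sorted_probs = probs[order]
    pos = np.searchsorted(sorted_probs, probs * (1 + 1e-12), side="right")
    pvals = np.minimum(csum[np.maximum(pos - 1, 0)], 1.0)
    return hets, pvals


def _hwe_het_distribution(n_a: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given allele count
    ``n_a`` out of 2n alleles, via the standard mid-out recurrence."""
    n_a = min(n_a, 2 * n - n_a)
    if n_a == 0:
        return np.array([1.0]), np.array([0])
    hets = np.arange(n_a % 2, n_a + 1, 2)
    probs = np.zeros(len(hets))
    # start at the mode-ish midpoint and recur outward
    mid = n_a * (2 * n - n_a) / (2.0 * n)
    i0 = int(np.argmin(np.abs(hets - mid)))
    probs[i0] = 1.0
    # P(h+2)/P(h) = (h_hom_A * h_hom_a * 4) / ((h+2)(h+1)) with hom counts at h
    for i in range(i0, len(hets) - 1):
        h = hets[i]
        hom_a = (n_a - h) // 2
        hom_A = n - h - hom_a
        probs[i + 1] = probs[i] * 4.0 * hom_A * hom_a / ((h + 2.0) * (h + 1.0))
    for i in range(i0, 0, -1):
        h = hets[i]
        hom_a = (n_a - h) // 2
        hom_A = n - h - hom_a
        probs[i - 1] = probs[i] * h * (h - 1.0) / (4.0 * (hom_A + 1.0) * (hom_a + 1.0))
    probs /= probs.sum()
    return probs, hets


def _hard_calls(dosage_col: np.ndarray, tol: float = 0.1) -> np.ndarray:
    """Round dosages to genotypes; entries farther than ``tol`` from an
    integer are treated as missing for HWE counting."""
    g = np.rint(dosage_col)
    g[np.abs(dosage_col - g) > tol] = np.nan
    return g


def filter_variants(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_p_min: float = 1.0e-3,
    miss_max: float = 0.02,
    drop_ambiguous: bool = True,
) -> tuple[list[str], dict[str, int]]:
    """Apply variant QC in order: strand-ambiguity, missingness (strict <),
    MAF (strict >), HWE exact p (strict >).  Returns surviving variant ids
    and a per-rule removal tally."""
    if len(genotypes.variants) == 0:
        raise ValueError("empty genotype matrix")
    counts = {"ambiguous": 0, "missingness": 0, "maf": 0, "hwe": 0}
    survivors: list[str] = []
    for j, row in genotypes.variants.iterrows():
        d = genotypes.dosage[:, j]
        if drop_ambiguous and is_strand_ambiguous(row["allele1"], row["allele2"]):
            counts["ambiguous"] += 1
            continue
        miss = np.isnan(d).mean()
        if not miss < miss_max:
            counts["missingness"] += 1
            continue
        obs = d[~np.isnan(d)]
        if obs.size == 0:
            counts["missingness"] += 1
            continue
        af = obs.mean() / 2.0
        maf = min(af, 1.0 - af)
        if not maf > maf_min:
            counts["maf"] += 1
            continue
        g = _hard_calls(obs)
        g = g[~np.isnan(g)]
        n_aa = int((g == 2).sum())
        n_Aa = int((g == 1).sum())
        n_AA = int((g == 0).sum())
        if not hwe_exact_test(n_AA, n_Aa, n_aa) > hwe_p_min:
            counts["hwe"] += 1
            continue
        survivors.append(str(row["variant_id"]))
    return survivors, counts


@dataclass
class PGSResult:
    raw: pd.Series  # index = subject ids
    n_matched: int
    n_flipped: int
    unmatched: list[str] = field(default_factory=list)


def compute_pgs(genotypes: GenotypeMatrix, weights: pd.DataFrame) -> PGSResult:
    """score_i = sum_j w_j * dosage_ij(effect allele).

    ``weights`` columns: variant_id, effect_allele, weight.  The dosage is
    flipped (2 - d) when the effect allele is allele1; weights whose effect
    allele matches neither variant allele, or whose variant is absent, are
    reported as unmatched and skipped.  Missing dosages are imputed at
    2 * (effect-allele frequency among non-missing calls).
    """
    var = genotypes.variants.set_index("variant_id")
    score = np.zeros(len(genotypes.subjects))
    n_matched = n_flipped = 0
    unmatched: list[str] = []
    for _, w in weights.iterrows():
        vid, ea, wt = str(w["variant_id"]), str(w["effect_allele"]).upper(), float(w["weight"])
        if vid not in var.index:
            unmatched.append(vid)
            continue
        j = var.index.get_loc(vid)
        a1 = str(var.iloc[j]["allele1"]).upper()
        a2 = str(var.iloc[j]["allele2"]).upper()
        d = genotypes.dosage[:, j]
        if ea == a2:
            eff = d
        elif ea == a1:
            eff = 2.0 - d
            n_flipped += 1
        else:
            unmatched.append(vid)
            continue
        obs = eff[~np.isnan(eff)]
        fill = obs.mean() if obs.size else 1.0  # 2 * effect-allele frequency
        eff = np.where(np.isnan(eff), fill, eff)
        score += wt * eff
        n_matched += 1
    if n_matched == 0:
        raise ValueError("no weight rows matched the genotype matrix")
    return PGSResult(
        raw=pd.Series(score, index=pd.Index(genotypes.subjects, name="subject_id")),
        n_matched=n_matched,
        n_flipped=n_flipped,
        unmatched=unmatched,
    )


def standardize_scores(raw: pd.Series, groups: pd.Series) -> pd.Series:
    """Within-group z-scores (sample SD, ddof=1): mean 0, SD 1 per group."""
    raw, groups = raw.align(groups, join="inner")
    out = pd.Series(np.nan, index=raw.index, dtype=float)
    for g, idx in raw.groupby(groups).groups.items():
        x = raw.loc[idx]
        if len(x) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"group {g!r} has zero score variance")
        out.loc[idx] = (x - x.mean()) / sd
    return out
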