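"""Synthetic ABCD-like cohort generator with recorded ground truth.

The generator emulates the structure the association battery needs without
any restricted data: 21 data-collection sites; siblings sharing families
(families wholly within one site); biallelic genotypes in Hardy–Weinberg
proportions at drawn MAFs; per-SNP effect weights that define 11 latent
polygenic scores; age/sex/10-level household income covariates; and a
latent hyperbolic discount rate per subject,

    log k_i = mu + scale * ( sum_j beta_j PGS_z_ij + covariate terms
                             + site + family + residual ),

where the bracketed budget has unit variance when ``resid_sd`` is left to
be completed automatically, so the configured ``true_effects`` are
standardized effect sizes on the latent log k.  A configured fraction of
subjects are non-systematic responders (uniform-random choices in the
task), some subjects carry the problematic-genotyping-batch flag, some are
missing task data completely at random, and a configurable number of
families are split across two sites — each exercising one cohort-assembly
exclusion rule.

Every draw descends from a single seed via ``numpy`` SeedSequence spawning
(streams, in order: structure, genotypes, weights, covariates, latent,
flags, PCs), so runs are byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ancestry import PC_COLS

#: The 11 polygenic scores of the association battery.
DEFAULT_PGS_NAMES: tuple[str, ...] = (
    "delay_discounting",
    "externalizing",
    "positive_urgency",
    "negative_urgency",
    "sensation_seeking",
    "perseverance",
    "premeditation",
    "attentional_impulsivity",
    "nonplanning",
    "motor_impulsivity",
    "educational_attainment",
)

POPULATIONS = ("EUR", "AFR", "AMR")


@dataclass
class CohortConfig:
    """Study conditions of the simulated cohort."""

    n_subjects: int = 8982
    n_sites: int = 21
    family_size_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.80, 2: 0.17, 3: 0.03}
    )
    n_snps: int = 220                      # split evenly over the 11 PGS
    maf_range: tuple[float, float] = (0.10, 0.40)
    pgs_names: tuple[str, ...] = DEFAULT_PGS_NAMES
    true_effects: dict[str, float] = field(
        default_factory=lambda: {"delay_discounting": 0.15, "educational_attainment": -0.10}
    )
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": -0.05, "sex": 0.05, "income": -0.10}
    )
    site_sd: float = 0.10
    family_sd: float = 0.35
    resid_sd: float | None = None          # None -> complete the budget to variance 1
    frac_nonsystematic: float = 0.15
    frac_missing_task: float = 0.20
    frac_batch_flagged: float = 0.007
    n_split_families: int = 1
    population_weights: dict[str, float] = field(
        default_factory=lambda: {"EUR": 0.554, "AFR": 0.197, "AMR": 0.249}
    )
    pc_separation: float = 12.0            # centroid spacing, within-pop SD units
    logk_mean: float = -3.0                # ln k at the cohort centre (k ~ 0.05 / day)
    logk_scale: float = 1.5                # natural-log units per latent SD
    choice_inverse_temp: float = 0.5       # logistic choice noise, per dollar
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in [
            ("frac_nonsystematic", self.frac_nonsystematic),
            ("frac_missing_task", self.frac_missing_task),
            ("frac_batch_flagged", self.frac_batch_flagged),
        ]:
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.site_sd < 0 or self.family_sd < 0:
            raise ValueError("variance parameters must be non-negative")
        if self.resid_sd is not None and self.resid_sd < 0:
            raise ValueError("resid_sd must be non-negative")
        if self.n_sites > self.n_subjects:
            raise ValueError("n_sites must not exceed n_subjects")
        if not 0 < self.maf_range[0] < self.maf_range[1] < 0.5:
            raise ValueError("maf_range must be an interval within (0, 0.5)")
        probs = np.array(list(self.family_size_dist.values()), dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("family_size_dist must be a probability distribution")
        unknown = set(self.true_effects) - set(self.pgs_names)
        if unknown:
            raise ValueError(f"true_effects refer to unknown PGS: {sorted(unknown)}")

    def residual_sd(self) -> float:
        """resid_sd, completing the unit latent-variance budget if unset."""
        if self.resid_sd is not None:
            return self.resid_sd
        used = (
            sum(b**2 for b in self.true_effects.values())
            + sum(b**2 for b in self.covariate_effects.values())
            + self.site_sd**2
            + self.family_sd**2
        )
        if used >= 1.0:
            raise ValueError(
                "effect sizes and variance components exceed the unit latent "
                "variance budget; set resid_sd explicitly"
            )
        return float(np.sqrt(1.0 - used))


@dataclass
class TruthRecord:
    """Ground truth retained for parameter-recovery checks."""

    true_effects: dict[str, float]
    covariate_effects: dict[str, float]
    residual_sd: float
    true_log_k: pd.Series
    nonsystematic: pd.Series
    weights: dict[str, pd.DataFrame]       # PGS name -> (variant_id, effect_allele, weight)
    pgs_true: pd.DataFrame                 # cohort-standardized latent scores

    def to_json(self, path) -> None:
        payload = {
            "true_effects": self.true_effects,
            "covariate_effects": self.covariate_effects,
            "residual_sd": self.residual_sd,
            "true_log_k": self.true_log_k.to_dict(),
            "nonsystematic": {k: bool(v) for k, v in self.nonsystematic.items()},
            "weights": {k: v.to_dict(orient="list") for k, v in self.weights.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class Cohort:
    subjects: pd.DataFrame                 # one row per subject
    genotypes: "GenotypeMatrix"
    truth: TruthRecord
    config: CohortConfig

    @property
    def pcs(self) -> pd.DataFrame:
        return self.subjects.set_index("subject_id")[PC_COLS]


def _pop_centroids(separation: float) -> dict[str, np.ndarray]:
    """Three population centroids at mutual distance ``separation`` in the
    PC1-PC2 plane (within-population covariance is the identity)."""
    c = {p: np.zeros(len(PC_COLS)) for p in POPULATIONS}
    c["AFR"][0] = separation
    c["AMR"][0] = separation / 2.0
    c["AMR"][1] = separation * np.sqrt(3.0) / 2.0
    return c


def generate_reference_panel(
    n_per_pop: int, separation: float = 12.0, seed: int | None = None
) -> pd.DataFrame:
    """Labelled Gaussian PC clouds standing in for the three reference
    populations (one row per reference sample, PC1..PC10 + population)."""
    if n_per_pop < 11:
        raise ValueError(
            "n_per_pop must be >= 11: the per-population 10x10 PC covariance "
            "needs more samples than dimensions to be full rank"
        )
    rng = np.random.default_rng(seed)
    frames = []
    cents = _pop_centroids(separation)
    for pop in POPULATIONS:
        x = rng.standard_normal((n_per_pop, len(PC_COLS))) + cents[pop]
        df = pd.DataFrame(x, columns=PC_COLS)
        df["population"] = pop
        df.index = pd.Index([f"{pop}_{i:04d}" for i in range(n_per_pop)], name="IID")
        frames.append(df)
    return pd.concat(frames)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full cohort; see the module docstring for the latent model."""
    from .genetics import GenotypeMatrix  # local import to avoid cycles

    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_struct, rng_geno, rng_w, rng_cov, rng_lat, rng_flag, rng_pc = (
        np.random.default_rng(s) for s in streams
    )
    n = config.n_subjects

    # --- families and sites -------------------------------------------
    sizes_pool = np.array(sorted(config.family_size_dist), dtype=int)
    probs = np.array([config.family_size_dist[s] for s in sizes_pool], dtype=float)
    max_size = int(sizes_pool.max())
    draws = rng_struct.choice(sizes_pool, size=n // min(sizes_pool) + max_size, p=probs)
    sizes = []
    total = 0
    for s in draws:
        if total + s > n:
            s = n - total
        if s == 0:
            break
        sizes.append(int(s))
        total += s
        if total == n:
            break
    n_fam = len(sizes)
    family_id = np.repeat([f"f{i:05d}" for i in range(n_fam)], sizes)
    fam_sites = rng_struct.integers(0, config.n_sites, size=n_fam)
    site_id = np.repeat([f"site{j:02d}" for j in fam_sites], sizes)
    subject_id = np.array([f"s{i:05d}" for i in range(n)])

    # split families across two sites to exercise the exclusion rule
    fam_sizes_arr = np.array(sizes)
    multi = np.flatnonzero(fam_sizes_arr >= 2)
    n_split = min(config.n_split_families, len(multi))
    fam_first = np.r_[0, np.cumsum(fam_sizes_arr)][:-1]
    if n_split > 0 and config.n_sites > 1:
        for fi in rng_struct.choice(multi, size=n_split, replace=False):
            row = fam_first[fi]  # move the first member to a different site
            current = fam_sites[fi]
            new = (current + 1 + rng_struct.integers(0, config.n_sites - 1)) % config.n_sites
            site_id[row] = f"site{new:02d}"

    # population per family (siblings share ancestry), PCs per subject
    pw = np.array([config.population_weights.get(p, 0.0) for p in POPULATIONS])
    pw = pw / pw.sum()
    fam_pop = rng_struct.choice(len(POPULATIONS), size=n_fam, p=pw)
    pop = np.array(POPULATIONS)[np.repeat(fam_pop, sizes)]
    cents = _pop_centroids(config.pc_separation)
    pcs = rng_pc.standard_normal((n, len(PC_COLS)))
    pcs += np.stack([cents[p] for p in pop])

    # --- genotypes and latent polygenic scores ------------------------
    m = config.n_snps
    mafs = rng_geno.uniform(*config.maf_range, size=m)
    dosage = rng_geno.binomial(2, mafs, size=(n, m)).astype(float)
    alleles = np.array([["A", "C"], ["A", "G"], ["T", "C"], ["T", "G"]])
    pick = rng_geno.integers(0, len(alleles), size=m)
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{100000 + j}" for j in range(m)],
            "chrom": (np.arange(m) % 22 + 1).astype(str),
            "pos": 1_000_000 + 137 * np.arange(m),
            "allele1": alleles[pick, 0],
            "allele2": alleles[pick, 1],
        }
    )
    genotypes = GenotypeMatrix(subjects=list(subject_id), variants=variants, dosage=dosage)

    per = m // len(config.pgs_names)
    if per < 1:
        raise ValueError("n_snps must be >= number of PGS")
    weights: dict[str, pd.DataFrame] = {}
    pgs_z = pd.DataFrame(index=pd.Index(subject_id, name="subject_id"))
    for i, name in enumerate(config.pgs_names):
        cols = slice(i * per, (i + 1) * per)
        w = rng_w.standard_normal(per)
        weights[name] = pd.DataFrame(
            {
                "variant_id": variants["variant_id"].iloc[cols].to_numpy(),
                "effect_allele": variants["allele2"].iloc[cols].to_numpy(),
                "weight": w,
            }
        )
        raw = dosage[:, cols] @ w
        pgs_z[f"pgs_{name}"] = (raw - raw.mean()) / raw.std(ddof=1)

    # --- covariates ----------------------------------------------------
    age = np.clip(rng_cov.normal(9.9, 0.63, size=n), 9.0, 11.0)
    sex = rng_cov.binomial(1, 0.53, size=n).astype(float)
    income = rng_cov.integers(1, 11, size=n).astype(float)

    def z(x):
        return (x - x.mean()) / x.std(ddof=1)

    cov_z = {"age": z(age), "sex": z(sex), "income": z(income)}

    # --- latent discount rate -------------------------------------------
    resid_sd = config.residual_sd()
    latent = np.zeros(n)
    for name, beta in config.true_effects.items():
        latent += beta * pgs_z[f"pgs_{name}"].to_numpy()
    for name, beta in config.covariate_effects.items():
        latent += beta * cov_z[name]
    site_codes, site_inv = np.unique(site_id, return_inverse=True)
    fam_codes, fam_inv = np.unique(family_id, return_inverse=True)
    latent += config.site_sd * rng_lat.standard_normal(len(site_codes))[site_inv]
    latent += config.family_sd * rng_lat.standard_normal(len(fam_codes))[fam_inv]
    latent += resid_sd * rng_lat.standard_normal(n)
    true_log_k = config.logk_mean + config.logk_scale * latent

    # --- flags -----------------------------------------------------------
    nonsys = rng_flag.random(n) < config.frac_nonsystematic
    batch = rng_flag.random(n) < config.frac_batch_flagged
    missing_task = rng_flag.random(n) < config.frac_missing_task

    subjects = pd.DataFrame(
        {
            "subject_id": subject_id,
            "family_id": family_id,
            "site_id": site_id,
            "age": age,
            "sex": sex,
            "income": income,
            "batch_flag": batch,
            "missing_task": missing_task,
            "population_true": pop,
            "true_log_k": true_log_k,
            "nonsystematic": nonsys,
        }
    )
    for j, c in enumerate(PC_COLS):
        subjects[c] = pcs[:, j]
    for c in pgs_z.columns:
        subjects[c] = pgs_z[c].to_numpy()

    truth = TruthRecord(
        true_effects=dict(config.true_effects),
        covariate_effects=dict(config.covariate_effects),
        residual_sd=resid_sd,
        true_log_k=pd.Series(true_log_k, index=subject_id),
        nonsystematic=pd.Series(nonsys, index=subject_id),
        weights=weights,
        pgs_true=pgs_z,
    )
    return Cohort(subjects=subjects, genotypes=genotypes, truth=truth, config=config)


@dataclass
class ExclusionLog:
    n_input: int
    n_batch: int
    n_missing_task: int
    n_cross_site_family: int
    n_retained: int

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


def apply_exclusions(
    subjects: pd.DataFrame, profile_ids=None
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Cohort-assembly exclusions, applied in order:

    1. drop subjects flagged as belonging to the problematic genotyping batch;
    2. drop subjects with missing task data (absent from ``profile_ids``, or
       ``missing_task`` when no profile list is given);
    3. drop every member of any family observed at more than one site.

    Idempotent; returns the retained subjects plus a per-rule count log.
    """
    df = subjects.copy()
    n0 = len(df)
    df = df[~df["batch_flag"].astype(bool)]
    n_batch = n0 - len(df)

    if profile_ids is not None:
        have = df["subject_id"].isin(set(map(str, profile_ids)))
    elif "missing_task" in df.columns:
        have = ~df["missing_task"].astype(bool)
    else:
        have = pd.Series(True, index=df.index)
    n_missing = int((~have).sum())
    df = df[have]

    sites_per_family = df.groupby("family_id")["site_id"].nunique()
    bad_fams = set(sites_per_family[sites_per_family > 1].index)
    n_cross = int(df["family_id"].isin(bad_fams).sum())
    df = df[~df["family_id"].isin(bad_fams)]

    log = ExclusionLog(
        n_input=n0,
        n_batch=n_batch,
        n_missing_task=n_missing,
        n_cross_site_family=n_cross,
        n_retained=len(df),
    )
    return df.reset_index(drop=True), log
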