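# Methods

`ddpgs` re-creates, on fully synthetic data with known ground truth, a
polygenic-score (PGS) association study of delay discounting in a
preadolescent multi-site cohort.  This note documents the models, the
defaults and why they were chosen, the numerical choices, and what the
synthetic cohort does and does not emulate.

## The task model

The Adjusting Delay Discounting Task presents, at each of seven delays
(6 h, 1 d, 1 wk, 1 mo, 3 mo, 1 y, 5 y; converted to days with 1 mo = 30 d,
1 y = 365 d so the discount rate is in day⁻¹), six choices between an
immediate amount and $100 delayed.  The immediate amount starts at $50 and
after choice *t* (t = 1..5) moves by 100/2^(t+1) dollars — down if the
immediate option was chosen, up otherwise; the indifference point (IP) is
the amount after the sixth choice corrected by half the final step
(±100/2⁷).  The precise adjustment schedule of the original computerised
task is not published; this decreasing-step titration is the standard
adjusting-amount algorithm consistent with its qualitative description,
and it is the package's reference behaviour.  For a deterministic agent
with a monotone value function it is exact bisection, so

    |IP − present value| ≤ A / 2⁷ = $0.78125,

which is the fidelity bound the verification battery enforces.

Simulated respondents are hyperbolic discounters valuing the delayed
reward at `A·g(D)`, `g(D) = 1/(1 + kD)`, choosing the delayed option with
probability `logistic(β_temp · (A·g(D) − immediate))`.  The inverse
temperature `β_temp` defaults to 0.5 /$: choices far from indifference are
then nearly deterministic while near-indifference choices are noisy, which
produces realistic occasional non-monotonicity without destroying the
signal.  Non-systematic responders (default 15% of the cohort) choose
uniformly at random on every trial; this is the mechanism the
bounce-criterion filters are meant to catch.

## Phenotypes

Three outcomes per subject:

* **k, log k** — least-squares fit of `IP_d/A` to `1/(1 + k D_d)` with
  k ∈ [10⁻⁸, 10].  The SSE is minimised by a 64-point log-spaced grid scan
  followed by bounded Brent refinement on the bracketing interval;
  deterministic, and verified against a 10⁶-point grid search.  `log k` is
  the natural log (the base is a documented convention; it only rescales
  coefficients).  A flat profile at the maximum clamps k to the lower
  bound and sets a boundary flag.
* **AUC** — trapezoid area under the IP curve with delays normalised to
  [0, 1] and IPs to [0, 1]; 1 = no discounting.
* **log-delay AUC** — same with `x = log10(1+D)/log10(1+D_max)`; the
  `1+D` offset keeps the transform defined and order-preserving for the
  6-hour delay.  Both variants prepend a (0, 1) anchor: at zero delay the
  subject is indifferent by construction.  This keeps the area in [0, 1];
  it is a convention switch users can audit in `compute_auc`.

## Non-systematic response QC

A *reversal* is an IP that exceeds the preceding IP (ascending delays) by
strictly more than 20% of the delayed amount.  The lenient filter removes
subjects with more than one reversal, the conservative filter removes any
reversal; the retained sets are provably nested.  Only the bounce rule is
implemented; the companion last-versus-first-delay criterion from the same
QC tradition is not used by this analysis design and is excluded.

## Genetics

Variant QC applies, in order: strand-ambiguous removal (allele pair A/T or
C/G), missingness < 2% (strict), MAF > 5% (strict, from non-missing
dosages), and Hardy–Weinberg exact-test p > 10⁻³.  The HWE test is the
conditional exact test on hard genotype calls (dosages rounded; entries
more than 0.1 from an integer treated as missing), computed by the
standard mid-out recurrence over heterozygote counts; it is exact where
the chi-square approximation degrades and is verified against full
log-factorial enumeration for every table with n ≤ 200.

A PGS is `Σ_j w_j · dosage_ij(effect allele)` over matched weight rows,
flipping the dosage (2 − d) when the effect allele is the variant's other
allele and mean-imputing missing dosages at twice the effect-allele
frequency.  Bayesian shrinkage of GWAS weights is upstream and out of
scope: weights are an input (the synthetic truth tables, or any
user-supplied table).  Scores are z-standardised within each genetic
ancestry group (sample SD), which is what makes betas comparable across
groups without embedding mean PGS differences between them.

## Ancestry assignment

Each subject's first 10 PCs are compared with per-population reference
means and covariances; the subject is assigned to the population with the
smallest squared Mahalanobis distance (monotone-equivalent to the raw
distance), ties broken by the model's fixed population order.
Per-population covariance is used rather than pooled because the clouds
may differ in spread; an ill-conditioned covariance (condition number
> 10⁸) is ridge-regularised.  PCA itself is upstream: PCs are consumed,
never computed from genotypes here.

## The association model

For each (PGS, outcome) pair within an ancestry group:

    outcome_z = β·PGS_z + age + sex + income + PC1..PC10
                + b_site + b_family + ε,

with random intercepts for data-collection site and for family nested in
site, fitted by REML.  Both the predictor and the outcome are
z-standardised within the group by default (`standardize="both"`), so β
is in SD units; `"predictor"` and `"none"` reproduce outcome-scale
conventions.  Income enters as a numeric 1–10 ordinal.

The REML engine exploits the structure of the marginal covariance
(block-diagonal by site; family blocks plus a rank-one site term within a
site) through two nested Woodbury identities, so each likelihood
evaluation is O(n·p) with no dense matrix.  β and σ² are profiled out;
the two variance ratios are optimised on the log scale by Nelder–Mead
from method-of-moments starts (fixed tolerances; deterministic).  A ratio
optimised to the lower bound (≈ e⁻³⁰) is a boundary fit — the model
degenerates gracefully to family-only or OLS, and at ratios exactly zero
the profiled solution reproduces OLS to machine precision.  Fixed-effect
inference is Wald with the normal reference; with thousands of subjects
and ≥ 20 sites the calibration is verified empirically (type-I error and
p-value uniformity under the null) rather than through small-sample df
corrections, which are out of scope.  The engine is cross-checked against
statsmodels `MixedLM` (same REML optimum, variance components and
log-likelihood) and against a dense-matrix GLS oracle for β and SE.

Marginal R² follows the Nakagawa–Schielzeth definition:
`var(Xβ̂) / (var(Xβ̂) + σ²_site + σ²_family + σ²_resid)`; the reported
delta is R²m(full) − R²m(covariate-only) with both models fitted on
identical rows (rows dropped for a missing predictor force a reduced-model
refit on the matching rows).

The battery crosses 11 scores with 3 outcomes (33 tests) per group and
adjusts p-values by Benjamini–Hochberg within group at q ≤ 0.05.  One
model per score; no joint multi-PGS model.

## The synthetic cohort

The generator emulates the structural features the inference needs:

* 21 sites; families of size 1–3 (defaults 80/17/3%) drawn i.i.d. and
  assigned wholly to one site; a configurable number of families is then
  split across two sites to exercise the cross-site exclusion rule.
* Biallelic genotypes in Hardy–Weinberg proportions at MAFs drawn from
  (0.10, 0.40); 20 SNPs per score with N(0,1) weights define 11
  independent latent scores.  The defaults avoid the QC thresholds so the
  scoring path is exercised end to end; QC violations are constructed
  explicitly in tests.
* Covariates: age ~ N(9.9, 0.63) years (the cohort's age band), sex
  (53% male), income ordinal 1–10 uniform.
* Latent discount rate:
  `log k = −3.0 + 1.5·(Σ β_j PGS_z + covariate terms + site + family + resid)`,
  with site SD 0.10, family SD 0.35, and the residual SD completed so the
  bracketed budget has unit variance.  The configured effects are
  therefore *standardized* effects on latent log k, and the default
  centre/scale put k between roughly 0.003 and 1 day⁻¹ — the range the
  7-delay task resolves.  Planted defaults: +0.15 (delay-discounting
  score) and −0.10 (educational-attainment score), matching the reference
  recovery conditions used throughout the verification battery.
* Exclusion fodder: 0.7% batch-flagged subjects, 20% missing task data
  (completely at random — the real missingness mechanism is unreported),
  15% non-systematic responders.
* Ancestry: three Gaussian PC clouds (identity covariance, centroids an
  equilateral triangle of side `pc_separation` = 12 within-population SDs)
  with population weights 55.4/19.7/24.9% (EUR/AFR/AMR-like); families
  share a population.

**What this does not emulate** — linkage disequilibrium, imputation
quality, allele-frequency differences between populations (genotypes are
drawn identically across ancestry groups), genotype–PC confounding
(population stratification), assortative mating, and any real demographic
structure beyond the fields used.  Passing tests therefore demonstrate
that the *pipeline machinery* is correct and calibrated under the stated
generative model; they cannot certify robustness to stratification or LD
artefacts in real data.

## Reference study conditions and problem sizes

The verification battery (tests and `scripts/acceptance.py`) uses: 200
deterministic agents for staircase fidelity; 1000 (tests) / 500 (script)
random profiles for the AUC oracle and 200/50 for the 10⁶-point k-grid
oracle; 10⁴ profiles for QC recounts; all HWE tables to n = 200 (tests;
n = 120 in the script); parameter recovery at n = 3000, 20 sites, families
1–3, β = 0.15 with 100/30 replicates; null calibration with 500/100
replicate cohorts, each contributing the 11 independent score tests; 200/60
all-null 33-test batteries at n = 1500 and 20/10 truth-positive batteries
at n = 3000; and 40/20 replicates for the sign-structure check.  These
sizes are the package's reference conditions; they keep the full battery
in the tens of minutes on a single CPU while leaving Monte-Carlo error
well inside each acceptance band.

Because BH controls the false discovery *rate*, truth-positive batteries
are expected to admit an occasional non-planted flag (about 5% of
discoveries); the battery check therefore asserts the pooled non-planted
flag share (≤ 10%) and the planted-effect power (≥ 0.8), not literal
emptiness of the non-planted set, which no FDR procedure guarantees.

## Known limitations

* Wald/normal p-values: no Satterthwaite or Kenward–Roger correction; not
  recommended below ~10 sites or a few hundred subjects.
* The staircase model has no catch trials, reaction times or attention
  checks; non-systematic behaviour is purely the random-responder mixture.
  One visible consequence: noisy-but-systematic simulated agents rarely
  produce exactly one large reversal, so the conservative filter removes
  barely more than the lenient one (both retain ~86–90% at the defaults),
  whereas real preadolescent data lose far more under the any-reversal
  rule.  The filters' set-nesting and counting logic is what the tests
  certify, not the attrition rate.
* The k fit assumes the hyperbolic form; exponential or hyperboloid
  discounters are out of scope.
* Exact tie-breaks: equidistant ancestry assignments take the first
  population in model order; BH ties resolve by the stable sort.
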