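# Methods

## The threshold model and its identification

Case-control status is modelled through a latent liability
l_i = w_i′β + x_i′g + e_i with standard-normal residuals; an individual is a
case exactly when l_i exceeds the threshold. Because a probit-type binary
model identifies neither the residual variance nor the threshold, both are
fixed (σ²_e = 1, t = 0) and the unpenalized intercept absorbs prevalence.
Covariates are dummy-coded against reference levels female / never-smoker /
first region; age is standardized for sampling (the sampler mixes better when
all unpenalized columns share a scale) and handled on its natural scale in
the logistic comparator.

The sampler is an augmented Gibbs scheme: liabilities from one-sided
truncated normals; coefficients by a single-site (Gauss–Seidel) scan of
univariate normal full conditionals — the joint multivariate-normal full
conditional is honoured in distribution while avoiding p×p solves; 1/τ²_j
from an inverse-Gaussian; λ² from a Gamma. All design columns are centered
internally (the intercept absorbs the means). Centering changes no reported
quantity — coefficients and the mean liability are parametrization-invariant
— but decouples the intercept from the coefficient scan, which is what makes
single-site updates mix. The kernel is compiled with numba so the
protocol-scale chains (tens of thousands of iterations, hundreds of SNPs)
stay practical on a single core.

Correctness is pinned by an independent oracle in the test suite: a
deterministic 2-d grid integration of the exact (β₀, g) posterior at p = 1
(fixed λ², where the marginal SNP prior is exactly double-exponential), which
the Gibbs posterior mean must match within 3 Monte-Carlo standard errors.
The hierarchy is written so that the same model is expressible in
general-purpose Gibbs samplers (probit likelihood + ddexp prior + Gamma
hyperprior) for external cross-checking.

## The shrinkage hyperprior — the one genuinely open choice

The double-exponential prior's rate is √λ², and λ² carries a Gamma(a, b)
hyperprior. The published analysis states the Gamma form but not (a, b), and
the choice matters more than any other knob in the model: with a weakly
informative hyperprior (e.g. a = 1, b = 0.1) the hierarchy equilibrates at a
λ² low enough that null-SNP sign probabilities track their unshrunk probit
z-scores, and the Pr > 0.8 rule selects ~20% of pure-noise SNPs at the scales
this package targets — behaviour incompatible with a selection rule that
flagged only ~4% of a real panel.

The default therefore auto-calibrates an informative hyperprior at the
universal-threshold scale: prior mean λ²₀ = 2 ln(p) · mean_j(x_j′x_j) with
shape a = 2p (rate b = a/λ²₀), the Laplace analogue of requiring noise
coefficients to be shrunk below the noise ceiling of a p-dimensional scan.
The shape is chosen comparable to the p likelihood terms so the prior binds
while λ² remains a sampled quantity that yields to strong data (many true
effects inflate Στ²_j and pull λ² down). Under this default, simulated
cohorts of 1,000 with 300 SNPs and five |g| = 0.35 effects are recovered
completely with ≈1 false selection, and null panels select 2–4% of SNPs at
the 0.8 cutoff. Explicit (lambda2_shape, lambda2_rate) switch back to the
fully data-driven hierarchy; fix_lambda2 freezes the rate entirely.
Sensitivity in one line: weaker hyperpriors monotonically enlarge the
selected set; anyone using the selection probabilities should report the
hyperprior alongside the cutoff.

## Observed-scale odds ratios

Disease probabilities per genotype use the threshold-model transformation
p = Φ(μ_l + c·g_j − t). μ_l is taken as the per-iteration mean linear
predictor over the sample **minus the focal SNP's own mean contribution**
(x̄_j·g_j), so substituting genotype c does not double-count the SNP; the
signature OR removes the mean contributions of all selected SNPs and
contrasts two copies of every risk allele against two copies of every
protective one. The variant that leaves the focal contribution inside μ_l
differs only by a factor common to numerator and denominator genotypes of
the same SNP and is not exposed. Summaries report posterior mean, median,
kernel-density-argmax mode, and equal-tail 95% intervals; Pr(OR > 1)
accompanies the signature.

## Convergence

Geweke's diagnostic compares the first 10% of a chain with the last 50%,
standardized by spectral-density-at-zero variance estimates
(Bartlett-kernel-weighted autocovariances, lag window √n). |z| > 1.96 flags
non-convergence; λ², the mean liability, and the largest |coefficient| chain
are monitored by default. Constant chains report z = 0 with a warning.

## Synthetic cohorts

Genotypes are drawn per LD block from an equicorrelated Gaussian copula
thresholded at the Hardy–Weinberg quantiles of each SNP's MAF (drawn
uniformly from maf_range). Marginals are exactly HW; between-SNP genotype
correlation is controlled only stochastically, and discretization attenuates
it — latent ρ = 0.95 yields genotype r² ≈ 0.69 at MAF 0.3, so blocks meant to
trip the r² > 0.8 pruning filter need ρ ≈ 0.99. Covariates are categorical
draws with liability-scale effects; the default current-smoker coefficient
0.95 is the probit-scale counterpart of an odds ratio near 5, the
conventional size of the smoking effect on bladder-cancer risk; occasional
and former smoking get 0.2 and 0.5, gender 0.2, and age 0.1 per standardized
unit. Ages are uniform on 40–80 and used continuously (BTL, logistic) or in
three groups <60 / 60–70 / ≥70 (AUC-RF; boundaries rounded upward).
Individuals are accepted by rejection sampling until the case and control
quotas fill — the draw conditions on the case-control design, so raw
prevalence is a by-product. Missingness is completely at random.

What the simulator does **not** emulate: realistic haplotype structure
(equicorrelated blocks, not coalescent LD decay), population stratification,
genotyping-batch artefacts, or informative missingness. Passing recovery
tests therefore demonstrate correctness of the estimators under the model's
own assumptions, not robustness to real-data pathologies.

A fixed covariate table reproduces the study population profile exactly
(1,047 cases / 988 controls; all printed gender, smoking, and region margins,
including the never-smoker panel). The printed smoking categories sum to 6
cases and 4 controls fewer than the stratum totals; those rows carry missing
smoking status rather than invented categories. Joint structure beyond the
printed margins is arbitrary but deterministic.

## QC chain

Fixed order: sample call-rate (> 0.95 strictly, per the "more than 95%
successfully genotyped" rule) → SNP missingness (≤ 5% retained) → MAF ≥ 5%
with Fisher-exact rescue of rarer SNPs showing case-control association
(allelic 2×2 by default; genotypic behind a flag) → kNN imputation →
X-chromosome exclusion → greedy LD pruning at r² > 0.8. Counts reconcile
exactly at every stage and pruning is idempotent.

Imputation uses k = 3 and simple-matching distance over mutually observed
SNPs (the SCRIME-style default for categorical genotype data); modal ties
break toward the smaller code, distance ties by sample order. r² is the
squared Pearson correlation of additive codes (composite LD) — haplotype-ML
r² is a known dialect difference. The pruner keeps the earlier SNP of an
offending pair in annotation order; constant SNPs count as r² = 0 and are
logged. The Hardy–Weinberg exact test enumerates heterozygote counts
conditional on allele counts (probability-ordering two-sided p) and is used
for reporting in the control stratum by default, as an exclusion filter
(p < 1e-4) only in replication-style configurations. PCA on standardized
genotypes emits two component scores for visual stratification checks and
never excludes automatically.

## AUC-RF

Forests delegate to scikit-learn (bootstrap, Gini splits, mtry = ⌊√m⌋,
exposed OOB decision function and impurity importances); with fully grown
trees the OOB probability average coincides with vote counting. MDG is
reported on scikit-learn's normalized scale — the relative importance
MDG/max(MDG), which downstream reporting uses, is invariant to that
normalization. Elimination drops ⌊0.2·size⌋ (at least one) of the *initial*
full-model ranking per step — re-ranking each step is available behind a
flag — recording each subset's OOB AUC down to 10 variables inclusive of the
final undersized subset; ties in maximal AUC go to the smaller subset. The
OOB-AUC of the optimal subset is upward-biased by selection (measured on
permuted labels in the tests: mean excess ≲ 0.1 at n = 400, larger at
smaller n); it is a model-selection score, not an honest accuracy estimate.

## Logistic comparator

Per-SNP IRLS to gradient norm < 1e-8 (cap 100 iterations, damped steps);
Wald trend test by default, likelihood-ratio behind a flag; OR_aa/AA =
exp(2β) from the additive fit, matching the convention of pairing a single
homozygote OR with a trend p; a 2-df genotype-factor variant is available.
Quasi-complete separation is flagged at fitted |log-odds| > 15. Bonferroni
multiplies by the number of SNPs tested, capped at 1.

## Problem sizes in the validation suites

The test suite exercises the samplers at reduced but structurally faithful
sizes chosen as the package's own validation protocol: the Gibbs-vs-grid
oracle at n = 60, p = 1 with 30k iterations; BTL recovery at n = 1,000,
p = 300, five causal SNPs, 15k/3k iterations over 10 replicates (independent
SNPs, emulating the post-pruning analysis-ready matrix — strong LD spreads a
signal across neighbours and dilutes single-coefficient sign probabilities,
which is precisely why pruning precedes the fit); null calibration at
n = 400, p = 50 over 20 replicates; AUC-RF recovery at n = 1,000, p = 200
with 500 trees over 10 replicates; trend-test calibration over 1,000 null
SNPs at n = 1,000. The acceptance script runs a single end-to-end pipeline
at n = 800, p = 160 with graded effects (|g| = 0.15–0.5) plus separate null
studies.

## Known limitations

- Additive inheritance only; no interaction terms (including smoking × SNP).
- The selection probability is a one-sided tail mass, not a posterior
  inclusion probability; its operating characteristics depend on the λ²
  hyperprior as described above.
- Single-chain inference with Geweke checks; no multi-chain R-hat.
- The copula simulator's LD is exchangeable within blocks; methods whose
  behaviour depends on realistic LD decay should be validated elsewhere.
- PLINK support is text (.ped/.map) read-only; no binary .bed, VCF, or
  chip-vendor formats.
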