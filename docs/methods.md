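# Methods

## Setting and model

`mr2s` performs two-sample Mendelian randomization: the effect of an
exposure (a quantitative trait, measured in SD units) on a binary outcome
is estimated from per-SNP association summaries taken from two independent
GWAS. Writing γⱼ for instrument *j*'s true effect on the exposure and αⱼ
for its direct effect on the outcome, the observed summaries are modeled as

    β̂_exp,j ~ N(γⱼ, σ²_exp,j),    β̂_out,j ~ N(θ γⱼ + αⱼ, σ²_out,j),

independent across studies (no sample overlap). θ is the causal log odds
ratio per SD of exposure; a valid instrument has αⱼ = 0. All estimators
report θ̂ with a normal-theory 95% interval (θ̂ ∓ 1.959964·SE) and the
exponentiated odds-ratio scale.

## Instrument selection

The funnel applies, in order: (1) exposure significance p < `p_exposure`
(default 5×10⁻⁸); (2) greedy LD clumping — repeatedly retain the
lowest-p unprocessed SNP (ties broken lexicographically by identifier for
determinism) and discard unprocessed SNPs on the same chromosome within
`clump_window_kb` (default 10, inclusive on both ends) with r² ≥ `clump_r2`
(default 0.001); (3) proxy substitution for index SNPs absent from the
outcome table: the available SNP with maximal r² above `proxy_r2_min`
(default 0.8), accepted only if it has its own exposure record — the
index SNP's exposure association is never transplanted; (4) removal of
SNPs with p < 10⁻⁵ for the outcome or for any supplied confounder trait
(exclusion-restriction guard); (5) allele harmonization.

Harmonization resolves identical, swapped, and opposite-strand allele
codings deterministically. Palindromic (A/T, C/G) variants are
label-ambiguous: they are aligned by effect-allele frequency when the MAF
is below `palindrome_maf_max` (default 0.3) in both studies and dropped as
ambiguous otherwise. Missing r² in the LD reference is treated as 0
(unlinked), which is conservative for clumping on sparse references.
Every stage conserves counts (kept + dropped = input) and every drop
carries a machine-readable reason, so the per-trait cascade can be
reported exactly.

Indels and multi-allelic variants are rejected at parsing: frequency-based
palindrome logic is defined only for single-nucleotide biallelic variants.
Genomic coordinates are treated as opaque beyond the clumping window (no
build liftover, no strand inference from a reference genome).

## Estimators

**Wald ratio** β̂_out/β̂_exp with first-order delta-method SE
σ_out/|β̂_exp|, matching the weighting used by IVW (a second-order option
adds the exposure-noise term but is off by default for internal
consistency). **IVW** is WLS through the origin with weights 1/σ²_out; the
headline variant is multiplicative random effects, whose SE is inflated by
√max(1, Q/(k−1)) — never below the fixed-effect SE. **Weighted median**
uses the interpolated 50% weighted percentile of the per-SNP ratios
(inverse-variance weights β̂²_exp/σ²_out normalized to one, cumulative
weight evaluated at observation midpoints); its SE is a seeded parametric
bootstrap (default 1,000 replicates) resampling both summary vectors from
their sampling distributions. **MR-Egger** orients instruments to positive
β̂_exp, fits WLS with an intercept, and floors the multiplicative residual
dispersion at 1 so the coefficient SEs never undershoot the fixed-effect
ones; the intercept estimates mean directional pleiotropy. P-values are
two-sided normal by default; a t-distribution on k−2 df is available as a
dialect switch because reference implementations differ.

**cML-MA-BIC.** For each candidate invalid count K, the summary likelihood
above is maximized subject to "at most K of the αⱼ nonzero" by coordinate
updates: at the current θ the K instruments with the largest squared
standardized residuals (β̂_out − θβ̂_exp)²/(σ²_out + θ²σ²_exp) receive a
free α (their likelihood contribution vanishes), the remaining γⱼ are
profiled analytically, and θ is refit by weighted regression on the valid
set, iterating to convergence with seeded random restarts (default 3)
against local optima of the combinatorial set choice. BIC(K) =
K·log(n_eff) − 2·loglik; n_eff defaults to the smaller of the two study
sizes. The package reports both the BIC-selected estimate and the
model-averaged one (weights ∝ exp(−BIC/2); Buckland variance combining
within- and between-model spread). The SE at each K comes from the
numerically differentiated curvature of the profile log-likelihood.
Non-convergence at any K is flagged on the result, never silent.

## Sensitivity diagnostics

**Cochran's Q** uses ratio-scale weights β̂²_exp/σ²_out around a supplied
pooled estimate (minimized at the fixed-effect IVW value), with a
chi-square upper tail on k−1 df. **MR-PRESSO** computes the observed
weighted residual sum of squares with each SNP predicted from the IVW fit
that excludes it, builds the null by parametric simulation around the
leave-one-out fitted model (leave-one-out slopes refitted per draw,
vectorized), and reports the empirical global exceedance, per-SNP
empirical p-values with Bonferroni outlier calls at `outlier_alpha`/k, the
outlier-removed IVW estimate, and a distortion p-value comparing the
observed estimate shift against removal of random same-sized SNP subsets
(the literature does not pin this null down; this operationalization is
documented here and seeded). Note the empirical p floor is 1/(n_sim+1), so
n_sim must exceed k/α for outlier calls to be reachable. **Leave-one-out**
recomputes the multiplicative-random-effects IVW without each instrument
in turn. Funnel (ratio vs precision) and scatter (effect vs effect with SE
bars) tables are exported as numbers; no figure rendering is part of the
tested surface.

## Strength and power

PVE = 2·EAF·(1−EAF)·β² per instrument on the standardized scale;
F = [PVE·(n−1−k)]/[(1−PVE)·k] with n the exposure sample size (the
minimum across instruments when per-SNP sizes differ, which is the
conservative choice) — reported both jointly and per-SNP (k = 1).
Binary-outcome power uses the normal approximation
Φ(√(n·PVE·cf·(1−cf))·|log OR| − z₀.₉₇₅) with cf the outcome case
fraction; this is the approximation behind the widely used online MR power
calculators and is labeled as such.

## Synthetic data

The generator draws MAF ~ U(`maf_range`), γⱼ ~ N(0, `gamma_sd`²) (default
0.02, a realistic per-SD effect spread for a well-powered quantitative
blood trait), and standard errors 1/√(2·maf·(1−maf)·n) on the standardized
scale. Size presets carry the three study scales the package emulates: a
563,085-sample quantitative-trait meta-analysis (`bcx`), a 3,757-sample
founder-population immune-profiling GWAS (`sardinian`), and a
47,429-case / 68,374-control disease GWAS (`imsgc`), entered as its
effective size 4/(1/cases + 1/controls) ≈ 112,011 — the one deliberate
simplification relative to real case-control GWAS standard errors.

Pleiotropy models on a random `prop_invalid` subset: *balanced*
α ~ N(0, `alpha_sd`²); *directional* α ~ N(`alpha_mean`, `alpha_sd`²)
**defined on the exposure-increasing allele** and mapped back to the
reported coding by the sign of γⱼ — directional pleiotropy means the
direct effects share a sign once instruments are oriented the way MR fits
orient them, and defining it on the raw allele coding would instead cancel
in expectation; *correlated* (InSIDE-violating) α = `alpha_mean`·γⱼ +
N(0, `alpha_sd`²), with `alpha_mean` reinterpreted as the slope on γ.
Defaults `alpha_mean` 0.05 and `alpha_sd` 0.02 give direct effects roughly
ten times a typical outcome SE — strong, detectable pleiotropy.

A configurable fraction of variants (default 0.2) is palindromic, and the
outcome study presents each variant on a randomly swapped allele pair half
the time, so harmonization is genuinely exercised end to end. Reported
allele frequencies are identical in both studies (no frequency sampling
noise), which makes palindrome alignment exact; real data would add
frequency noise and occasional mis-alignment near the MAF threshold. LD is
block-diagonal with a single within-block r²; no realistic LD decay is
attempted. Passing tests on these data demonstrate correctness of the
statistical machinery under the assumed model, not robustness to
real-data pathologies (population stratification, sample overlap,
winner's curse from selecting and estimating in the same exposure study).

## Pipeline decision rule

The headline estimate is IVW-MRE (Wald ratio for a single instrument).
The Bonferroni threshold is 0.05 divided by the number of traits in the
run, recomputed per invocation. A *contradiction* is flagged when any
pleiotropy-robust estimator (weighted median, Egger slope, cML, PRESSO-
corrected) is nominally significant with the opposite sign to the
headline, or the Egger intercept has p < 0.05 — an operationalization of
"no contradictory sensitivity results", which qualitative rule admits
several readings. Verdicts: `robust` (headline p below Bonferroni, no
contradiction), `suggestive` (p < 0.05), `null`, `insufficient` (zero
surviving instruments; never an exception). Reverse-direction runs first
remove instruments inside the MHC window (default chr6:25–35 Mb,
configurable), whose extended LD and pervasive immune pleiotropy make
instruments there untrustworthy, and report the excluded count.

## Numerical choices and problem sizes

All stochastic procedures (median bootstrap, PRESSO simulations, cML
restarts, the generator) take explicit integer seeds and are bitwise
reproducible. Empirical p-values use the (1 + #exceed)/(n_sim + 1)
convention, so they are never zero. P-values are floored at the smallest
positive double; ratio p-values for β = 0 are exactly 1. Clumping and
proxy ties are broken by (p-value, snp_id) so outputs are order-stable.
The simulation studies in the test suite and acceptance script use 150 to
1,000 replicates with 30 instruments — sizes at which Monte-Carlo error
is a few times smaller than the tolerances being asserted, chosen so the
whole suite runs on a laptop in a few minutes.

## Known limitations

No multivariable MR, mode-based estimation, or Steiger filtering; no
VCF/BGEN genotype parsing (LD is consumed precomputed); no genome-build
liftover; the power formula and case-control effective-n are
approximations; the cML coordinate search is heuristic over a
combinatorial space — restarts mitigate but cannot eliminate local
optima.
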