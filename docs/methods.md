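# Methods

## Model and estimand

For n unrelated females, a gene's J SNPs are coded as minor-allele
counts g_ij ∈ {0, 1, 2}. Writing the heterozygote genotypic value as
γ ∈ [0, 2] (the mean degree of XCI skewing over the gene's SNPs), the
per-SNP value decomposes exactly as g_ij(γ) = γ·1{g_ij ≥ 1} +
(2−γ)·1{g_ij = 2}. With Beta-density weights ω_j = Beta(MAF̂_j; 0.5,
0.5), the weighted burden therefore splits into two regressors x1
(weighted carrier burden) and x2 (weighted homozygote burden), and the
working GLM

    h(μ) = β0 + βc⁽¹⁾ x1 + βc⁽²⁾ x2 + bᵀz

identifies γ = βc⁽¹⁾/βc with βc = (βc⁽¹⁾+βc⁽²⁾)/2. When the per-SNP
skewness degrees γ_j differ, the estimand is their weighted mean with
effective weights ω_j·(#carriers_j − #homozygotes_j) — i.e. weights
proportional to the number of heterozygous carriers, since only
heterozygotes carry information about skewing.

γ is defined only for trait-associated genes (βc ≠ 0). All interval
estimates are reported on [0, 2]; the Fieller and penalized sets are
truncated to it, the Bayesian posterior is supported on it.

### Identification caveat

The burden collapse is a *working* model: it is exactly correct when
per-SNP effects are proportional to the weights (β_j = βc·ω_j) and the
effect directions agree. When effects have mixed signs or magnitudes
uncorrelated with the weights, the probability limit of the coefficient
ratio is not γ but a projection-weighted compromise, and no amount of
data removes that gap. This matters for interpreting the simulation
study below.

## Estimators

**Fieller (GF).** The Wald pivot for H0: γ = γ0 is inverted in closed
form: the confidence set is {γ0 : A γ0² + B γ0 + C ≤ 0} with
A = βĉ² − z²·V̂(βĉ), B = 2(z²·Ĉ(βĉ⁽¹⁾,βĉ) − βĉ⁽¹⁾βĉ),
C = (βĉ⁽¹⁾)² − z²·V̂(βĉ⁽¹⁾). Geometry by the sign of A and the
discriminant: a bounded interval (A>0, Δ>0), the complement of one
(A<0, Δ>0 — a two-piece "discontinuous" set), the whole line (A<0,
Δ<0), or empty (A>0, Δ<0). Degenerate rows the four-case display omits
are handled explicitly: A = 0 solves the linear inequality; |Δ| <
1e−12 is treated as a point set at the vertex. Classification (empty /
noninformative = [0,2] / discontinuous / point / regular) is assigned
*after* truncation, since the study metrics are computed on truncated
sets; the endpoint test for "noninformative" uses a 1e−10 slack. The
width of a two-piece set is the sum of piece lengths; a point set has
width 0.

**Penalized Fieller (PF).** Maximizing
pl(βc0) = −(βĉ−βc0)²/(2V̂(βĉ)) + λ·log|βc0| gives the closed-form
penalized denominator β̃c = βĉ/2 + sign(βĉ)·√(βĉ²/4 + λV̂(βĉ)), with
shrinkage factor ξ = β̃c/(2β̃c−βĉ) and V̂(β̃c) = ξ²V̂(βĉ) (the O(n⁻³)
remainder is dropped). The numerator is bias-corrected,
β̃c⁽¹⁾ = βĉ⁽¹⁾ + γ̃(β̃c−βĉ) with γ̃ = βĉ⁽¹⁾/β̃c untruncated, and its
moments follow the delta-method displays

    V̂(β̃c⁽¹⁾) = ξ⁻²V̂(βĉ⁽¹⁾) − 4(ξ⁻¹−1)γ̃Ĉ + 4(1−ξ)²γ̃²V̂(βĉ),
    Ĉ(β̃c⁽¹⁾,β̃c) = Ĉ − 2ξ(1−ξ)γ̃V̂(βĉ).

The exponent reading (ξ⁻², ξ⁻¹−1) is fixed by the λ→0 limit: as the
penalty vanishes, ξ→1 and every correction term must die, leaving the
plain Fieller quantities (verified by a dedicated limit test). With the
default λ = z²₁₋α/₂/4 the leading quadratic coefficient of the PF set
is provably positive (it reduces to βĉ²/4 + λV̂ > λV̂), so the
pre-truncation set is always one bounded interval — the penalized
method cannot produce discontinuous sets. Conventions: sign(0) = +1 in
β̃c (flagged); a negative computed V̂(β̃c⁽¹⁾) (possible through the
subtraction term) is floored at 0 and flagged.

**Bayesian (GBN / GBU).** Independent priors: γ ~ normal(1, 1)
truncated to [0, 2] (GBN; "both parameters 1" read as mean 1, SD 1) or
γ ~ U(0, 2) (GBU); β0, βc, b ~ N(0, 10²); σ ~ Exp(1) (quantitative).
The sampler is an adaptive random-walk Metropolis on unconstrained
parameters — γ through a scaled logit with Jacobian, σ through a log —
run as several vectorized chains. The proposal covariance is
re-estimated from pooled warm-up history every 200 iterations and
per-chain step sizes follow a Robbins–Monro recursion toward a 0.3
acceptance target; both freeze at the end of warm-up, so the sampling
kernel is fixed and has the posterior as stationary distribution.
Chains initialize at the GLM MLEs with γ at the truncated Fieller point
(or 1 when undefined). Split-R̂ and effective sample size are computed
with `arviz`; R̂ > 1.05 on γ raises a convergence warning. For
quantitative traits the Gaussian log-likelihood inside the sampler is
evaluated through the sufficient statistics (DᵀD, Dᵀy, yᵀy), making
each step O(p²) regardless of n; this is algebraically identical to
the full likelihood.

The point estimate is the mode of a boundary-corrected KDE of the γ
draws: density f(g) + f(−g) + f(4−g) on a 1024-point grid over [0, 2],
with f a Gaussian KDE whose reference-rule (Scott) bandwidth is
computed from the *original* draws. Computing the bandwidth on the
mirrored triple would inflate it roughly fourfold and drag interior
modes to the boundary — the reflected-sample reading fails the
truncated-normal recovery check (mode 0.2 estimated as 0.0), so the
original-sample rule is the committed definition. The credible interval
is the shortest window containing ⌈(1−α)·S⌉ sorted draws (HPDI).

**GLM layer.** Quantitative fits are OLS with the unbiased n−p residual
mean square in the coefficient covariance (the MLE σ̂² differs by
O(p/n) and is immaterial at the study's n). Logistic fits use
Newton/IRLS with the inverse observed information (equal to expected
information at the MLE for the canonical link), tolerance 1e−8, 100
iterations; separation is flagged when any |coefficient| exceeds 30 and
the replicate is recorded as failed rather than silently truncated. No
regularization enters the GLM itself; penalization exists only inside
the PF estimator.

## Synthetic-data generator

The generator emulates a single trait-associated gene in n unrelated
females:

* **MAFs** — common SNPs ~ U(0.01, 0.5); rare SNPs ~ U(0.005, 0.01);
  the rare fraction η occupies ⌊ηJ⌋ random positions. Defaults J = 100,
  η ∈ {0, 0.4, 1}.
* **Genotypes** — each haplotype thresholds a stationary latent AR(1)
  Gaussian vector (corr ρ^|j−k|, ρ = 0.5, simulated by the Markov
  recursion); the minor allele is called above the (1−MAF) quantile.
  Two independent haplotypes per subject give Hardy–Weinberg marginals
  with linkage-disequilibrium-like local correlation.
* **Skewing** — heterozygote codes are replaced by the replicate's true
  γ (all SNPs share one γ per replicate; truths are drawn U(0, 2)).
* **Effects** — |β_j| = e·|log10 MAF_j|/2 with e = 1.5 (rare) or 1.1
  (common); ⌊τJ⌋ random SNPs get positive signs, the rest negative
  (τ ∈ {0.6, 1}).
* **Traits** — quantitative: y = β0 + Σβ_j g_ij(γ) + δQ + ε with
  β0 = δ = 0.5, Q ~ N(0,1), ε ~ N(0, σ²), σ = 1. Case–control:
  Bernoulli-logit with the same linear predictor, subjects accrued
  sequentially until exactly n/2 cases and n/2 controls (surplus
  discarded; 10⁶-subject safety cap).

Analysis of each replicate re-estimates MAFs from the simulated sample
(columns with estimated MAF > 0.5 are flipped to minor-allele coding;
monomorphic columns get MAF clipped to 1/(2n+1) for weight evaluation
only), rebuilds weights and burdens, fits the working GLM with Q as a
covariate, and runs the requested estimators.

**Metrics.** Per method over replicates: MSE of the (truncated) point
estimate against the per-replicate truth; coverage (an empty set never
covers, the noninformative set [0, 2] always covers); width mean /
median / SD / IQR over nonempty sets (two-piece widths sum their
pieces); proportions of empty, noninformative and discontinuous sets;
proportions of point estimates exactly 0 or exactly 2.

### What the generator does and does not emulate

The generator reproduces allele-frequency spectra, local LD,
Hardy–Weinberg genotypes, covariate confounding, and the XCI-S coding.
It does not emulate genotyping error, missingness, relatedness,
population structure, or per-SNP heterogeneity of γ (a heterogeneous-γ
mode exists but is excluded from the study metrics, which need a single
per-replicate truth).

### Discrepancy with the published description of this design

This generator follows its published description to the letter, and an
independent R re-implementation of one replicate (lm/dbeta, no shared
code) agrees with it. Under these conditions, however, the burden
working model is strongly misspecified: with 100 causal common SNPs of
the stated magnitudes the fitted signal is roughly an order of
magnitude stronger than the published interval widths imply, and with
40% negative effect signs the coefficient-ratio limit itself scatters
around the truth (an n-independent MSE floor near 0.12). The published
results table reports values (e.g. Fieller MSE 0.129 at n = 500
falling to 0.041 at n = 2000 with 95% coverage) that this design
cannot produce at any sample size; they are consistent instead with a
much weaker, sign-aligned effective signal. The code behind the
published table evidently differed from its description. We keep the
described design — it is the only specification available — and report
the honestly computed quantities; `scripts/acceptance.py` documents the
replicate counts used. Consequently, estimator-calibration checks
(coverage, parameter recovery) are tested against data generated from
the working model itself, where 95% Fieller coverage is exact (verified
at 400 replicates), while the study generator exercises the estimators
under realistic misspecification.

## Numerical choices

* Fieller: |Δ| < 1e−12 → point set; noninformative endpoint slack
  1e−10; classification precedence empty → noninformative →
  discontinuous → point → regular.
* A = B = 0: the inequality is constant; C ≤ 0 gives [0, 2], else the
  empty set.
* PF with zero denominator variance: penalization is a no-op (warned);
  degenerate variances collapse the PF set to the plain point estimate.
* Ratio 0/0 (βĉ⁽¹⁾ = βĉ = 0): point estimate NaN with a degeneracy
  flag; such replicates are excluded from point metrics and counted.
* Sampler: proposal covariance floor 1e−10·I; initialization jitter
  0.01; seeds derive from a `SeedSequence` so replicates are
  independent and the whole study is reproducible from one integer.
* MCMC profiles: "full" 8 chains × 10,000 draws (5,000 warm-up);
  "desk" 4 × 4,000 (2,000 warm-up). The study runner and acceptance
  script use the desk profile with 150–500 replicates; at these sizes
  the KDE mode and HPDI add Monte-Carlo noise of a few hundredths,
  small against the replicate-level spread.
* QC: exact conditional Hardy–Weinberg test (enumeration over
  heterozygote counts of matching parity), call-rate 0.99 per SNP and
  per individual, MAF floor 1e−5. Samples with any missing call inside
  a gene are dropped before estimation (the model has no missing-data
  mechanism).
* Rank-based inverse normal transform: Blom offsets,
  Φ⁻¹((r − 3/8)/(n + 1/4)), average ranks for ties.

## Known limitations

* The gene-level γ is a weighted mean; per-SNP skewness degrees are not
  recoverable, and skew toward disease vs normal alleles cannot be
  distinguished (the target allele is always the minor one).
* γ is meaningless for genes with no trait association; the CLI expects
  a pre-screened gene list.
* Independent females only; no pedigree or mixed-model support.
* The logit-link case–control route needs larger samples for the same
  interval calibration, mirroring the usual efficiency gap.
* Random inactivation and escape both give γ = 1 and cannot be told
  apart without male data.
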