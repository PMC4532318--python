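# Methods

## The classical twin design

Variance in each trait is decomposed into additive-genetic (A),
shared-environmental (C) or dominance (D), and nonshared-environmental (E)
influences, identified by the contrast between monozygotic twins (who share
all segregating DNA) and same-sex dizygotic twins (who share half on
average). The latent components of a pair correlate 1.0 / 0.5 (A), 1.0 / 1.0
(C), 1.0 / 0.25 (D) and 0 / 0 (E) across MZ / DZ co-twins. E absorbs
measurement error; C and D are never co-estimated because twins reared
together cannot identify all four sources simultaneously. Opposite-sex pairs
are outside the package's scope: the analysis set is filtered to same-sex
pairs, and quantitative sex limitation (separate path magnitudes per sex) is
fitted to the same-sex groups.

## Synthetic cohorts

`simulate_twin_pairs` draws each latent factor vector per pair as bivariate
standard normal with the component's cross-twin correlation, then maps it
through the lower-triangular path matrices; the paper-trail quantity is the
implied covariance `aa' + cc' (+ dd') + ee'` within person and its
component-scaled counterpart across twins. The generator adds, in order:

- **confounder covariates** — individual-level scores (unit variance) with
  their own heritability and an arbitrary correlation among themselves; each
  loads linearly on every phenotype. Because the covariates are heritable
  and shared across traits, they induce genetic covariance between
  phenotypes that regression adjustment can remove — this is what the
  negative-affect analysis exercises.
- **sex and age effects** — additive shifts on centred sex (0/1) and age
  (uniform on [16, 17], the cohort age band).
- **positive skew** — the monotone map `x = expm1(τ·y)` per phenotype, so
  that the standard `log(x + 1)` preprocessing step linearizes it exactly.
  τ defaults between 0.12 and 0.45 across the fixture phenotypes, giving
  right tails of roughly the magnitude questionnaire scales show.
- **missingness** — per-cell completely-at-random deletion at a configurable
  rate (default 0), to exercise the row-wise likelihood.

The packaged fixture (`make_fixture_cohort`) emulates an adolescent twin
questionnaire study: three psychotic-like-experience scales and two
sleep-disturbance scales generated from an AE structure with published
standardized A components (0.51, 0.45, 0.44, 0.41, 0.41) and published
PLE–sleep genetic (0.48–0.60) and nonshared-environmental (0.19–0.28)
correlations, 1,722 MZ and 1,553 DZ pairs by default. Correlations the
source tables do not determine are package defaults chosen once: PLE–PLE
r_A = 0.60 and r_E = 0.30, sleep–sleep r_A = 0.80 and r_E = 0.60 (the two
sleep scales correlate ~0.7 phenotypically, so their etiological overlap
must be high), covariate heritability 0.4, covariate intercorrelation 0.45,
and covariate loadings 0.5 on every phenotype (phenotype–covariate
correlations ≈ 0.55, inside the 0.4–0.7 band negative-affect measures show).

What the generator does *not* emulate: ordinal item structure and floor
effects, rater differences, ascertainment and nonresponse, opposite-sex
pairs, and sex-specific genetic architecture. Passing tests therefore
demonstrate correctness of the estimators under the stated Gaussian
generative model, not robustness to those real-data features.

## Preprocessing

Positively skewed measures are log-transformed (`log(x + offset)`, default
offset 1 because questionnaire scores have zero minima; the offset is
configurable). Nuisance covariates — sex and age by default, plus any
confounder scores — are regressed out of each phenotype in a single joint
OLS over stacked individuals, deliberately ignoring pair clustering, as is
conventional for twin-model preprocessing; residuals are standardized to
mean 0, variance 1 over the analysis set. Individuals missing a covariate
are dropped from the regression and keep a missing residual. Standardization
is computed over the whole analysis set rather than within sex or zygosity
strata. Designs with condition number above 1e8 are rejected as collinear.

## Saturated model

Per zygosity group the 2p-dimensional stacked twin vector gets a Gaussian
mean and covariance, optionally constrained so that means and variances are
equal across the two twins of a pair, the within-twin covariance blocks are
equal, and the cross-twin block is symmetric (which pools the two asymmetric
cross-trait cross-twin cells — the package's pooling rule). These
constraints make the admissible set invariant under the twin-swap
permutation, so the complete-data constrained MLE is available in closed
form as the twin-symmetrized sample moments; with missing cells an ECM loop
(conditional-moment E-step, symmetrized M-step, tolerance 1e−10 on −2LL,
max 500 iterations) is used. Twin correlations and cross-trait cross-twin
correlations are read off the constrained covariance; confidence intervals
are a seeded percentile bootstrap over pairs (default 1,000 resamples) —
bootstrap rather than profile likelihood because every entry of the
saturated covariance would otherwise need its own profile.

Two parameter-count conventions coexist deliberately: the *constrained*
saturated fit (used for correlations) and the *unconstrained* fit (used as
the −2LL baseline for model comparison; at five phenotypes it has
2 × (10 + 55) = 130 free parameters across the two zygosity groups).

## Biometric models

The Cholesky likelihood is full-information: rows are grouped by missingness
pattern and each group contributes through its sufficient statistics, so an
objective evaluation costs a handful of p-dimensional factorizations
regardless of sample size. Optimization is L-BFGS-B with finite-difference
gradients, bounded only by the sign convention (diagonal path entries
nonnegative, resolving the Cholesky sign indeterminacy; the E diagonal is
floored at 1e−6, which keeps every implied covariance positive definite
since Σ ± cross-block is then a sum of Gram matrices with a full-rank E
term). Starting values invert the twin-covariance moment equations from the
constrained saturated fit (e.g. Σ_A = 2(B_MZ − B_DZ) for ACE), project each
component to the nearest positive-definite matrix, and take Cholesky
factors; five seeded random restarts (25% relative perturbation) guard
against local optima, and identical seeds reproduce identical fits.
Estimates with a non-E diagonal below 1e−4 are flagged as boundary
solutions. Degrees of freedom follow the observed-statistics convention:
df = number of non-missing data cells − free parameters.

Confidence intervals for correlated-factors quantities use the delta method
on the observed information (numeric Hessian at the optimum), which is exact
enough for interior solutions at these sample sizes and orders of magnitude
cheaper than profiling a 35-parameter surface; a pair bootstrap of the whole
fit is available by rerunning `fit_biometric` on resampled data when
boundary solutions make Wald intervals unreliable. Etiological correlations
are reported with sign (the underlying type admits [−1, 1] even though
published magnitudes are conventionally positive).

## Model comparison and selection

Nested models are compared by Δ(−2LL), χ²-distributed with Δdf equal to the
parameter-count difference (nesting is checked structurally: component
subset and compatible sex structure). A negative likelihood-ratio statistic
beyond 1e−6 relative tolerance is treated as an optimizer failure, not
rounded away. AIC is reported relative to the reference model as
Δχ² − 2Δdf; tables emit it against both the saturated baseline and the full
ACE/ADE model, labeled, since both conventions appear in practice. BIC uses
the degrees-of-freedom convention −2LL − df·ln(N) with N the number of twin
pairs (families); this differs from the parameter-count convention by a
dataset-wide constant, so orderings — the only quantity selection uses — are
identical. The ladder selects the lowest BIC, breaks ties toward fewer
parameters, and accepts dropped parameters when the χ² test is
nonsignificant at α = 0.05.

## Problem sizes and numerical tolerances

The test suite and acceptance harness run everything at sizes a laptop
handles in minutes: Monte-Carlo oracles use 2×10⁵–10⁵ pairs per zygosity
(tolerances scaled to ≥3 standard errors), calibration and power checks use
5–100 seeded replicates, and the parameter-recovery harness uses 100
replicates of 1,722 + 1,553 pairs, matching the cohort the fixture
emulates. Closed-form equivalences are asserted to 1e−8, parameterization
equivalence to 1e−6, and χ² tail probabilities to 1e−10 against a numeric
integration oracle.

## Known limitations

Ordinal/liability-threshold phenotypes, qualitative sex limitation,
opposite-sex pairs, gene–environment interaction and longitudinal models are
out of scope. Wald CIs can misbehave at variance-component boundaries (use
the bootstrap there). The ECM bootstrap for heavily missing data is slow
relative to the complete-data closed form. The saturated model's parameter
count reflects this package's constraint set, which need not match other
software's sex-structured saturated models.
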