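# Methods

## Data model

One record per coded video: the interaction context immediately
preceding the bite (one of eight labels: resources, benign, resting,
unpleasant, painful, territorial, public space, play), the bite
components entering the severity score, the interaction duration in
seconds, and victim / dog / setting covariates. Initiator and handler
sex may be missing (`NA` in CSV); every other field is required.
Behaviour coding is long-format scan sampling: one row per (video,
actor, ethogram code, 3-second window), windows indexed backwards from
the first bite, window `w` covering `(3w, 3(w+1)]` seconds before it.
A sparse table listing only positive marks is valid — absent
combinations mean "not observed".

## Severity score

`score = n·a + b + c`, where `n` counts bites, `a ∈ {1, 3}` encodes a
visible puncture (assumed absent when it cannot be ascertained),
`b ∈ {0, 1}` head shaking during the bite and `c ∈ {0, 1}` a hold
longer than one second. With several bites of different severity in one
video, each component takes its most extreme value across bites. The
score is an integer in `[n, 3n + 2]`; 5 is the ceiling for a single
bite.

## Behaviour time series

For each ethogram code the per-window occurrence proportion is computed
over the videos whose coded interaction still covers that window (the
"at-risk" denominator — videos have unequal coded lengths, and using
the full sample would conflate "not observed" with "not yet under
observation"). The series is truncated at window index 11 because 35 s
falls inside window 11's span and few interactions are coded longer.
Uncertainty is a Wilson score interval (well behaved at small
denominators and proportions near 0/1, both common late in the series;
evaluated through statsmodels). Smoothing is a centred 3-point moving
average with truncated end windows, preserving series length.

## Descriptives and reliability

Context cross-tabulations report within-level percentages across the
eight contexts plus totals. Per-context mean severity carries a
non-parametric bootstrap percentile CI: videos resampled with
replacement within context, B = 10,000 replicates by default, 2.5/97.5
percentiles, fully seeded. Observer agreement is unweighted Cohen's
kappa from the raters' confusion matrix (the compared variables are
nominal), banded with 0.61–0.80 as "acceptable"; perfect agreement with
degenerate marginals is defined as κ = 1.

## Hierarchical gamma regression

Severity is gamma distributed with a log link on the mean — the
mean/shape parameterisation `y ~ Gamma(shape = s, rate = s/μ)`,
`μ = exp(η)`, so the log link acts on the expectation. The linear
predictor contains a per-context intercept plus duration (z-scored;
effects are per sample SD), dog size, and optionally victim sex, victim
age, bite site and initiator, dummy-coded against the first observed
vocabulary level (references are recorded with every fit). Under
partial pooling `α_c ~ N(μ_α, σ_α²)`, shrinking sparse contexts toward
the grand mean; the fixed-effect variant gives each context an
independent `N(0, 10²)` intercept.

Priors: coefficients `N(0, 1)` (a deliberate regularising choice);
`μ_α ~ N(0, 10²)`, `σ_α ~ Half-Cauchy(5)`, `s ~ Gamma(0.01, 0.01)`.
Missing initiator values are latent Bernoulli indicators with a
Beta(1, 1) prior on the "victim initiated" proportion, sampled jointly,
so their uncertainty propagates into the coefficients.

**Sampler.** Adaptive Metropolis-within-Gibbs: exact Gibbs for `μ_α`
(conjugate normal), the latent indicators and their proportion;
random-walk Metropolis for intercepts and coefficients; log-scale
random walks for `σ_α` and `s` (with Jacobian terms). Proposal scales
adapt by Robbins–Monro toward 0.44 acceptance during warmup only, so
post-warmup draws come from a fixed kernel. Each update touches only
the rows its parameter affects; the current pointwise log-likelihood
vector is cached and stored per retained draw, giving the WAIC matrix
for free. Chains are seeded from a single `SeedSequence`, making runs
draw-identical given a seed.

**Diagnostics.** Split-chain Gelman–Rubin R̂ and autocorrelation-based
ESS (multi-chain autocovariance, Geyer initial-monotone-positive pair
truncation), cross-checked against arviz in the test suite. The
defaults flag R̂ ≥ 1.01 or ESS below target in the result rather than
raising; a production-quality run uses 4 chains × 5,000 post-warmup
draws, while tests and the acceptance script use shorter chains (2–4
chains × 800–2,500 draws) — enough for the tolerances they assert.

**Derived quantities.** 95% HDIs are the shortest interval containing
⌈0.95·n⌉ sorted draws. Contrasts are response-scale differences in
expected severity between two levels, other predictors at reference,
duration at its mean, context intercept at the grand mean; a contrast
is "significant" when its HDI excludes zero. The ICC uses the log-scale
residual variance of a gamma variate, trigamma(s):
`ICC = σ_α² / (σ_α² + ψ₁(s))` — one of several possible latent-scale
definitions; it is the one adopted here. The duration effect is
reported on both scales, explicitly labelled: `multiplier = exp(β)` per
SD, and the response-scale slope `μ(z+1) − μ(z)` at the baseline —
the two differ and are easy to conflate.

## Model selection

Candidates: the baseline (contexts varying + duration + dog size), all
2⁴ − 1 non-empty combinations of the four optional predictors, and a
fixed-context copy of the full model — 17 specs by default. The
published analysis describes thirteen added models, which no subset
rule over these four predictors reproduces exactly; the enumeration is
therefore configurable (pass any predictor subset or filter the list)
and the full enumeration is the default. WAIC is computed from the
pointwise log-likelihood matrix with log-sum-exp stabilisation, sample
variance (ddof = 1) for the penalty, reported on the deviance scale
(−2·elpd, lower is better); weights are `exp(−Δ/2)` normalised. Ties
rank fewer predictors first.

## Synthetic generator

The generator is the model's generative twin plus the marginals of the
coded sample: 143 videos by default, context frequencies at the
published total row, covariate marginals at the published
distributions, duration lognormal(3.51, 0.9) giving SD ≈ 56 s (matching
the reported duration SD) — positive and right-skewed like real clip
lengths, ~10% of initiator values masked at random. Generating
parameters (μ_α = 1.55, σ_α = 0.25, s = 2.0, modest covariate effects)
put expected severity near the scale of the published estimates; they
were fixed once when the generator was written. Severity draws are
rounded to integer scores (clamped to ≥ 1) and decomposed into
components by the smallest-bite-count preimage, which round-trips
exactly through the scoring rule.

What the generator does *not* emulate: real coder disagreement, breed
structure, correlation between context and covariates, video-editing
censoring of interaction starts, and the discreteness pattern of real
component combinations. Passing recovery tests therefore demonstrates
that the inference machinery is calibrated for data meeting the model's
assumptions, not that the published dataset meets them.

Behaviour panels draw per-window Bernoulli indicators from logistic
ramp curves (occurrence probability rising ~20–30 s before the bite for
ramping codes, flat otherwise), with coded lengths spread binomially
between 2 and 12 windows.

## Calibration and problem sizes

The recovery harness simulates, fits and compares repeatedly, reporting
bias, RMSE, mean posterior SD and 95%-HDI coverage per generating
parameter. The standard desk-scale run uses 200 videos × 20 replicates
with 2 chains × 800 draws; coverage is assessed per coefficient against
a binomial band (≥ 16/20) and bias as |bias|/posterior-SD averaged over
coefficients (< 0.5) — per-coefficient bias thresholds at this
replicate count sit near 2σ of Monte-Carlo noise and would fail a
correct sampler too often. A 4,000-video single fit was used during
development to confirm the absence of systematic coefficient bias.

## Numerical notes and limitations

- Gamma log-density computed directly via `gammaln`; WAIC columns with
  non-finite entries raise, naming the observation.
- Degenerate inputs: zero-variance duration raises with advice to drop
  the predictor; categoricals need ≥ 2 observed levels; varying
  intercepts need ≥ 2 observed contexts; empty contexts are omitted
  from bootstrap output.
- The integer score is modelled as continuous gamma; at small means the
  rounding/clamping of the generator slightly inflates the effective
  shape (visible as a mild upward shape bias in very large synthetic
  fits). The published analysis makes the same continuous-gamma choice.
- Handler sex is carried as data but never modelled.
- Component-wise Metropolis mixes adequately at this problem size
  (ESS a few hundred per 10k draws for the correlated intercepts);
  meeting an ESS > 10,000 target requires proportionally longer runs.
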