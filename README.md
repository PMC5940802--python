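# bitescope

Analysis pipeline for dog-bite videos coded from online footage: perceived
bite-severity scoring, scan-sampled pre-bite behaviour time series,
observer-reliability statistics, and a Bayesian hierarchical gamma
regression of bite severity with WAIC-based model selection. A synthetic
generator emulates the coded dataset, so every stage runs without the
original recordings or their coding sheets.

## Who this is for

Researchers in veterinary epidemiology and applied ethology who code
human–dog interactions from video — one record per video with the
interaction context (resources, benign, resting, unpleasant, painful,
territorial, public space, play), bite components and covariates, plus a
long-format scan-sampling table marking which ethogram behaviours occurred
in each 3-second window before the first bite.

## The model

**Severity score.** Perceived severity of a video is

```
score = n·a + b + c
```

with `n` the number of bites, `a = 3` if a puncture wound is visible
(1 otherwise), `b = 1` if the dog shook its head whilst biting, and
`c = 1` if it held on for more than one second. Across multiple bites the
most extreme value of each component enters the total.

**Severity regression.** Scores are gamma distributed with a log link on
the mean:

```
y_i ~ Gamma(shape = s, rate = s/μ_i),   log μ_i = α_{c(i)} + x_i'β
α_c ~ Normal(μ_α, σ_α²)                 (varying intercepts per context)
β_j ~ Normal(0, 1)
```

Covariates: interaction duration (z-scored, effect per SD), dog size,
victim sex and age, bite site, and who initiated the interaction (missing
values imputed in-model as latent Bernoulli indicators). Candidate models
(baseline + all combinations of the optional predictors, plus a
fixed-intercept contexts variant) are compared by WAIC and WAIC weights.
Inference is by adaptive Metropolis-within-Gibbs MCMC with split-R̂ / ESS
diagnostics, 95% HDI summaries, response-scale contrasts, and the
intra-class correlation σ_α² / (σ_α² + ψ₁(s)).

**Behaviour series.** Per 3-s window before the bite (truncated at 35 s),
the proportion of still-observed ("at risk") videos showing each ethogram
code, with Wilson 95% CIs and a 3-point moving average.

## Worked example

```python
from bitescope import (VideoSimConfig, simulate_videos, fit, ModelSpec,
                       MCMCConfig)
from bitescope.hier_model import expected_severity_draws, icc, duration_effect, hdi
import numpy as np

records = simulate_videos(VideoSimConfig(n_videos=143, seed=1))
post = fit(records, ModelSpec(True, True, True, True),
           MCMCConfig(chains=4, draws=2500, warmup=1000, seed=2))

overall = expected_severity_draws(post, at="mean")
print("mean severity", round(float(np.mean(overall)), 2), 
      "HDI", [round(v, 2) for v in hdi(overall)])
print("ICC", round(icc(post)["mean"], 2))
print("duration x per SD", round(duration_effect(post)["multiplier"]["mean"], 2))
```

prints (seed-exact):

```
mean severity 4.39 HDI [3.51, 5.37]
ICC 0.05
duration x per SD 1.16
```

i.e. on this synthetic 143-video sample the population-average expected
severity is ≈4.4 points (95% HDI 3.5–5.4), contexts explain ≈5% of
severity variance, and each additional SD of interaction duration
multiplies expected severity by ≈1.2.

The same stages are available from the shell:

```
bitescope simulate --n-videos 143 --seed 1 --out-videos videos.csv
bitescope score --videos videos.csv --out severity.csv
bitescope fit --videos videos.csv --seed 2 --out posterior.json
bitescope select --videos videos.csv --seed 3 --out selection.csv
```

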