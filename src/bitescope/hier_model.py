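"""Bayesian hierarchical gamma regression of perceived bite severity.

Severity scores are modelled as gamma distributed with a log link on
the mean:

    y_i ~ Gamma(shape = s, rate = s / mu_i),   mu_i = exp(eta_i)
    eta_i = alpha_{c(i)} + x_i' beta

where ``c(i)`` is the interaction context of video ``i``.  Under
partial pooling the per-context intercepts are constrained by a common
distribution, alpha_c ~ Normal(mu_alpha, sigma_alpha^2), which shrinks
sparsely observed contexts toward the grand mean; the fixed-effect
variant gives every context an independent broad-prior intercept.
Coefficient priors are Normal(0, 1); remaining priors are broad
(mu_alpha ~ N(0, 10^2), sigma_alpha ~ Half-Cauchy(5),
s ~ Gamma(0.01, 0.01)).

Missing "who initiated the interaction" values are imputed inside the
model as latent Bernoulli indicators whose proportion parameter carries
a Beta(1, 1) prior and is sampled jointly with everything else.

Inference is by Markov chain Monte Carlo: an adaptive
Metropolis-within-Gibbs sampler with exact Gibbs updates where the
conditional is available (grand mean, latent initiator indicators and
their proportion) and adaptive random-walk Metropolis updates
elsewhere.  Convergence is monitored with the split-chain Gelman-Rubin
statistic and autocorrelation-based effective sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, polygamma

from .core_data import (
    BITE_SITES, CONTEXTS, DOG_SIZES, MISSING, SEXES, VICTIM_AGES, VideoRecord,
)
from .severity import score_records

__all__ = [
    "ModelSpec",
    "MCMCConfig",
    "DesignData",
    "ParameterSummary",
    "PosteriorSummary",
    "build_design",
    "log_likelihood",
    "fit",
    "hdi",
    "diagnostics",
    "split_rhat",
    "effective_sample_size",
    "contrasts",
    "icc",
    "expected_severity_draws",
    "duration_effect",
]

_OPTIONAL_PREDICTORS = ("victim_sex", "victim_age", "bite_site", "initiator")

_LEVELS = {
    "dog_size": DOG_SIZES,
    "victim_sex": SEXES,
    "victim_age": VICTIM_AGES,
    "bite_site": BITE_SITES,
}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: optional predictors plus the pooling mode.

    The baseline predictors — context, interaction duration and dog
    size — are always present.
    """

    include_victim_sex: bool = False
    include_victim_age: bool = False
    include_bite_site: bool = False
    include_initiator: bool = False
    context_pooling: str = "varying"

    def __post_init__(self) -> None:
        if self.context_pooling not in ("varying", "fixed"):
            raise ValueError("context_pooling must be 'varying' or 'fixed'")

    @property
    def optional_predictors(self) -> tuple[str, ...]:
        return tuple(
            name for name in _OPTIONAL_PREDICTORS
            if getattr(self, f"include_{name}")
        )

    @property
    def name(self) -> str:
        parts = ["base"] + list(self.optional_predictors)
        return "+".join(parts) + f"|{self.context_pooling}"


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 4
    draws: int = 5000
    warmup: int = 1000
    seed: int = 0
    target_ess: float = 10_000.0
    target_rhat: float = 1.01

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("chains must be >= 2")
        if self.draws <= 0 or self.warmup < 0:
            raise ValueError("draws must be > 0 and warmup >= 0")


@dataclass
class DesignData:
    """Design matrix and bookkeeping produced by :func:`build_design`."""

    y: np.ndarray
    context_index: np.ndarray
    context_labels: list[str]
    X: np.ndarray
    columns: list[str]
    reference_levels: dict[str, str]
    duration_mean_s: float
    duration_sd_s: float
    initiator_column: int | None
    missing_initiator_rows: np.ndarray
    video_ids: list[str]


def build_design(
    records: Sequence[VideoRecord],
    spec: ModelSpec,
    scores: Mapping[str, float] | None = None,
) -> DesignData:
    """Assemble the regression design for one model specification.

    Duration is standardised to z-scores (centred, divided by the
    sample SD) so its coefficient is a per-SD effect.  Categorical
    predictors are dummy-coded against a reference level (the first
    level of the controlled vocabulary observed in the data; the chosen
    references are recorded in ``reference_levels``).  Rows with a
    missing initiator are flagged for in-model imputation, not dropped.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if scores is None:
        scores = {s.video_id: float(s.score) for s in score_records(records)}
    y = np.array([scores[r.video_id] for r in records], dtype=float)
    if np.any(y < 1):
        raise ValueError("severity scores must be >= 1")

    observed_contexts = [c for c in CONTEXTS if any(r.context == c for r in records)]
    if spec.context_pooling == "varying" and len(observed_contexts) < 2:
        raise ValueError("varying-intercept pooling needs >= 2 observed contexts")
    ctx_pos = {c: i for i, c in enumerate(observed_contexts)}
    context_index = np.array([ctx_pos[r.context] for r in records], dtype=int)

    durations = np.array([r.interaction_duration_s for r in records], dtype=float)
    dur_sd = float(durations.std(ddof=1)) if len(records) > 1 else 0.0
    if dur_sd == 0.0:
        raise ValueError(
            "interaction durations have zero variance; drop the duration predictor"
        )
    dur_mean = float(durations.mean())

    columns: list[str] = ["duration_z"]
    design_cols: list[np.ndarray] = [(durations - dur_mean) / dur_sd]
    reference_levels: dict[str, str] = {}

    def add_dummies(field_name: str) -> None:
        levels_order = _LEVELS[field_name]
        observed = [
            lev for lev in levels_order
            if any(getattr(r, field_name) == lev for r in records)
        ]
        if len(observed) < 2:
            raise ValueError(
                f"predictor {field_name!r} has fewer than two observed levels"
            )
        reference_levels[field_name] = observed[0]
        for lev in observed[1:]:
            columns.append(f"{field_name}[{lev}]")
            design_cols.append(
                np.array(
                    [1.0 if getattr(r, field_name) == lev else 0.0 for r in records]
                )
            )

    add_dummies("dog_size")
    for name in ("victim_sex", "victim_age", "bite_site"):
        if name in spec.optional_predictors:
            add_dummies(name)

    initiator_column: int | None = None
    missing_rows = np.array([], dtype=int)
    if "initiator" in spec.optional_predictors:
        observed_vals = {r.initiator for r in records} - {MISSING}
        if len(observed_vals) < 2:
            raise ValueError("predictor 'initiator' has fewer than two observed levels")
        reference_levels["initiator"] = "dog"
        initiator_column = len(columns)
        columns.append("initiator[victim]")
        col = np.array(
            [
                1.0 if r.initiator == "victim" else 0.0  # missing start at 0
                for r in records
            ]
        )
        design_cols.append(col)
        missing_rows = np.array(
            [i for i, r in enumerate(records) if r.initiator == MISSING], dtype=int
        )

    X = np.column_stack(design_cols)
    return DesignData(
        y=y,
        context_index=context_index,
        context_labels=observed_contexts,
        X=X,
        columns=columns,
        reference_levels=reference_levels,
        duration_mean_s=dur_mean,
        duration_sd_s=dur_sd,
        initiator_column=initiator_column,
        missing_initiator_rows=missing_rows,
        video_ids=[r.video_id for r in records],
    )


def log_likelihood(y, mu, shape):
    """Gamma log-density with mean ``mu`` and shape ``s`` (rate s/mu)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(y <= 0) or np.any(mu <= 0) or shape <= 0:
        raise ValueError("y, mu and shape must all be positive")
    rate = shape / mu
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(y) - rate * y


def hdi(samples: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass * n)`` sorted draws."""
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    m = int(math.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("chains must be a (n_chains >= 2, n_draws) array")
    n = chains.shape[1]
    half = n // 2
    if half < 2:
        raise ValueError("chains too short to split")
    halves = np.vstack([chains[:, :half], chains[:, half: 2 * half]])
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of one chain via FFT."""
    n = x.size
    x = x - x.mean()
    size = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, size)
    acov = np.fft.irfft(f * np.conjugate(f), size)[:n].real
    return acov / n


def effective_sample_size(chains: np.ndarray) -> float:
    """Autocorrelation-based ESS (Geyer initial monotone sequence).

    Uses split chains, the multi-chain autocorrelation estimate
    rho_t = 1 - (W - mean autocovariance_t) / var_plus, paired-sum
    truncation at the first negative pair, and enforces monotone
    non-increasing pair sums.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("chains must be a (n_chains >= 2, n_draws) array")
    n = chains.shape[1]
    half = n // 2
    if half < 4:
        raise ValueError("chains too short for ESS estimation")
    halves = np.vstack([chains[:, :half], chains[:, half: 2 * half]])
    m, n = halves.shape
    chain_vars = halves.var(axis=1, ddof=1)
    W = chain_vars.mean()
    if W == 0:
        return float(m * n)
    B = n * halves.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    acov = np.mean([_autocovariance(c) for c in halves], axis=0)
    rho = 1.0 - (W - acov) / var_plus
    # Geyer: sum pairs rho_{2k} + rho_{2k+1}; stop at first negative pair,
    # then force the pair sums to be non-increasing.
    pair_sums = []
    t = 1
    while t + 1 < n:
        p = rho[t] + rho[t + 1]
        if p < 0:
            break
        pair_sums.append(p)
        t += 2
    running_min = np.inf
    tau = 1.0
    for p in pair_sums:
        running_min = min(running_min, p)
        tau += 2.0 * running_min
    return float(m * n / tau)


def diagnostics(chains: np.ndarray) -> tuple[float, float]:
    """(split R-hat, effective sample size) for one parameter's chains."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be 2-D (n_chains, n_draws)")
    lengths = {chains.shape[1]}
    if len(lengths) != 1:
        raise ValueError("chains must have equal length")
    return split_rhat(chains), effective_sample_size(chains)


@dataclass(frozen=True)
class ParameterSummary:
    name: str
    mean: float
    hdi_low: float
    hdi_high: float
    rhat: float
    ess: float


@dataclass
class PosteriorSummary:
    """Posterior draws, per-parameter summaries and diagnostics."""

    spec: ModelSpec
    config: MCMCConfig
    design: DesignData
    draws: dict[str, np.ndarray]  # name -> (chains, draws[, dim]) arrays
    summaries: list[ParameterSummary]
    log_lik: np.ndarray  # (chains * draws, n_obs)
    converged: bool
    convergence_notes: list[str] = field(default_factory=list)

    def draws_flat(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def summary(self, name: str) -> ParameterSummary:
        for s in self.summaries:
            if s.name == name:
                return s
        raise KeyError(name)


# ----------------------------------------------------------------------
# Sampler internals


class _AdaptiveScale:
    """Robbins-Monro step-size adaptation toward a target acceptance."""

    def __init__(self, scale: float = 0.5, target: float = 0.44):
        self.scale = scale
        self.target = target
        self.accepted = 0
        self.tried = 0
        self.batch = 0

    def update(self, accepted: bool) -> None:
        self.tried += 1
        self.accepted += accepted

    def adapt(self) -> None:
        if self.tried == 0:
            return
        self.batch += 1
        rate = self.accepted / self.tried
        self.scale *= math.exp((rate - self.target) / math.sqrt(self.batch))
        self.scale = min(max(self.scale, 1e-4), 50.0)
        self.accepted = 0
        self.tried = 0


def _half_cauchy_logpdf(sigma: float, scale: float = 5.0) -> float:
    return -math.log1p((sigma / scale) ** 2)


def _run_chain(
    design: DesignData,
    spec: ModelSpec,
    n_draws: int,
    warmup: int,
    rng: np.random.Generator,
):
    y = design.y
    log_y = np.log(y)
    X = design.X.copy()
    ctx = design.context_index
    K = len(design.context_labels)
    p = X.shape[1]
    n = y.size
    varying = spec.context_pooling == "varying"
    j_init = design.initiator_column
    miss = design.missing_initiator_rows
    impute = j_init is not None and miss.size > 0

    ctx_rows = [np.flatnonzero(ctx == k) for k in range(K)]
    col_rows = [np.flatnonzero(X[:, j] != 0) for j in range(p)]
    col_rows[0] = np.arange(n)  # duration affects every row
    if j_init is not None:
        col_rows[j_init] = np.arange(n)  # latent flips move this column

    # Initial state, jittered by the chain's RNG.
    base = float(np.log(y.mean()))
    alpha = np.full(K, base) + 0.1 * rng.standard_normal(K)
    mu_alpha = base + 0.1 * rng.standard_normal()
    sigma_alpha = float(np.exp(-1.0 + 0.2 * rng.standard_normal()))
    beta = 0.1 * rng.standard_normal(p)
    shape = float(np.exp(0.7 + 0.2 * rng.standard_normal()))
    p_init = 0.5
    if impute:
        z = rng.integers(0, 2, size=miss.size).astype(float)
        X[miss, j_init] = z

    eta = alpha[ctx] + X @ beta
    mu = np.exp(eta)

    def row_loglik(rows, mu_rows, s):
        rate = s / mu_rows
        return (
            s * np.log(rate) - gammaln(s) + (s - 1.0) * log_y[rows] - rate * y[rows]
        )

    row_ll = row_loglik(np.arange(n), mu, shape)

    scales = {f"alpha{k}": _AdaptiveScale(0.3) for k in range(K)}
    scales.update({f"beta{j}": _AdaptiveScale(0.3) for j in range(p)})
    scales["log_sigma"] = _AdaptiveScale(0.5)
    scales["log_shape"] = _AdaptiveScale(0.3)

    out = {
        "alpha": np.empty((n_draws, K)),
        "mu_alpha": np.empty(n_draws),
        "sigma_alpha": np.empty(n_draws),
        "beta": np.empty((n_draws, p)),
        "shape": np.empty(n_draws),
        "p_init": np.empty(n_draws),
        "log_lik": np.empty((n_draws, n)),
    }

    n_obs_init = 0
    n_init_victim_obs = 0
    if j_init is not None:
        observed_mask = np.ones(n, dtype=bool)
        observed_mask[miss] = False
        n_obs_init = int(observed_mask.sum())
        n_init_victim_obs = int(X[observed_mask, j_init].sum())

    total = warmup + n_draws
    for it in range(total):
        # --- per-context intercepts (random-walk Metropolis)
        for k in range(K):
            sc = scales[f"alpha{k}"]
            d = sc.scale * rng.standard_normal()
            rows = ctx_rows[k]
            mu_prop = mu[rows] * math.exp(d)
            ll_prop = row_loglik(rows, mu_prop, shape)
            if varying:
                prior = (
                    -0.5 * ((alpha[k] + d - mu_alpha) ** 2 - (alpha[k] - mu_alpha) ** 2)
                    / sigma_alpha**2
                )
            else:
                prior = -0.5 * ((alpha[k] + d) ** 2 - alpha[k] ** 2) / 100.0
            log_r = ll_prop.sum() - row_ll[rows].sum() + prior
            if math.log(rng.random()) < log_r:
                alpha[k] += d
                eta[rows] += d
                mu[rows] = mu_prop
                row_ll[rows] = ll_prop
                sc.update(True)
            else:
                sc.update(False)

        # --- grand mean of intercepts (exact Gibbs; varying pooling only)
        if varying:
            prec = K / sigma_alpha**2 + 1.0 / 100.0
            mean = (alpha.sum() / sigma_alpha**2) / prec
            mu_alpha = mean + rng.standard_normal() / math.sqrt(prec)

            # --- between-context SD (random walk on the log scale)
            sc = scales["log_sigma"]
            d = sc.scale * rng.standard_normal()
            sig_prop = sigma_alpha * math.exp(d)
            resid = alpha - mu_alpha
            ll_cur = -K * math.log(sigma_alpha) - 0.5 * (resid**2).sum() / sigma_alpha**2
            ll_prop = -K * math.log(sig_prop) - 0.5 * (resid**2).sum() / sig_prop**2
            log_r = (
                ll_prop - ll_cur
                + _half_cauchy_logpdf(sig_prop) - _half_cauchy_logpdf(sigma_alpha)
                + d  # Jacobian of the log transform
            )
            if math.log(rng.random()) < log_r:
                sigma_alpha = sig_prop
                sc.update(True)
            else:
                sc.update(False)

        # --- regression coefficients (random-walk Metropolis, N(0,1) priors)
        for j in range(p):
            sc = scales[f"beta{j}"]
            d = sc.scale * rng.standard_normal()
            rows = col_rows[j]
            xj = X[rows, j]
            mu_prop = mu[rows] * np.exp(d * xj)
            ll_prop = row_loglik(rows, mu_prop, shape)
            prior = -0.5 * ((beta[j] + d) ** 2 - beta[j] ** 2)
            log_r = ll_prop.sum() - row_ll[rows].sum() + prior
            if math.log(rng.random()) < log_r:
                beta[j] += d
                eta[rows] += d * xj
                mu[rows] = mu_prop
                row_ll[rows] = ll_prop
                sc.update(True)
            else:
                sc.update(False)

        # --- gamma shape (random walk on the log scale, Gamma(.01,.01) prior)
        sc = scales["log_shape"]
        d = sc.scale * rng.standard_normal()
        s_prop = shape * math.exp(d)
        ll_prop = row_loglik(np.arange(n), mu, s_prop)
        prior = (0.01 - 1.0) * (math.log(s_prop) - math.log(shape)) - 0.01 * (
            s_prop - shape
        )
        log_r = ll_prop.sum() - row_ll.sum() + prior + d
        if math.log(rng.random()) < log_r:
            shape = s_prop
            row_ll = ll_prop
            sc.update(True)
        else:
            sc.update(False)

        # --- latent initiator indicators (exact Gibbs) and their proportion
        if impute:
            b_init = beta[j_init]
            for idx, i in enumerate(miss):
                eta0 = eta[i] - b_init * X[i, j_init]
                mu0 = math.exp(eta0)
                mu1 = math.exp(eta0 + b_init)
                ll0 = float(row_loglik(np.array([i]), np.array([mu0]), shape)[0])
                ll1 = float(row_loglik(np.array([i]), np.array([mu1]), shape)[0])
                w1 = math.log(p_init) + ll1
                w0 = math.log1p(-p_init) + ll0
                m = max(w0, w1)
                prob1 = math.exp(w1 - m) / (math.exp(w0 - m) + math.exp(w1 - m))
                znew = 1.0 if rng.random() < prob1 else 0.0
                if znew != X[i, j_init]:
                    X[i, j_init] = znew
                    eta[i] = eta0 + b_init * znew
                    mu[i] = mu1 if znew else mu0
                    row_ll[i] = ll1 if znew else ll0
            n_victim = n_init_victim_obs + int(X[miss, j_init].sum())
            n_total = n_obs_init + miss.size
            p_init = float(rng.beta(1.0 + n_victim, 1.0 + n_total - n_victim))
        elif j_init is not None:
            p_init = float(
                rng.beta(1.0 + n_init_victim_obs, 1.0 + n_obs_init - n_init_victim_obs)
            )

        if it < warmup:
            if (it + 1) % 50 == 0:
                for sc in scales.values():
                    sc.adapt()
            continue

        t = it - warmup
        out["alpha"][t] = alpha
        out["mu_alpha"][t] = mu_alpha
        out["sigma_alpha"][t] = sigma_alpha
        out["beta"][t] = beta
        out["shape"][t] = shape
        out["p_init"][t] = p_init
        out["log_lik"][t] = row_ll

    return out


def fit(
    records: Sequence[VideoRecord],
    spec: ModelSpec = ModelSpec(),
    config: MCMCConfig = MCMCConfig(),
    scores: Mapping[str, float] | None = None,
    design: DesignData | None = None,
) -> PosteriorSummary:
    """Fit the hierarchical gamma regression by MCMC.

    Runs ``config.chains`` independent chains (seeded from
    ``config.seed``), summarises every parameter by posterior mean and
    95% HDI, computes split R-hat and ESS, and retains the pointwise
    log-likelihood matrix needed for WAIC.  The result carries explicit
    convergence flags; sampling never raises on non-convergence.
    """
    if design is None:
        design = build_design(records, spec, scores=scores)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chain_outputs = [
        _run_chain(design, spec, config.draws, config.warmup, np.random.default_rng(s))
        for s in seeds
    ]

    draws: dict[str, np.ndarray] = {}
    for name in ("alpha", "mu_alpha", "sigma_alpha", "beta", "shape", "p_init"):
        draws[name] = np.stack([c[name] for c in chain_outputs])
    log_lik = np.concatenate([c["log_lik"] for c in chain_outputs], axis=0)

    scalar_views: dict[str, np.ndarray] = {}
    for k, label in enumerate(design.context_labels):
        scalar_views[f"alpha[{label}]"] = draws["alpha"][:, :, k]
    if spec.context_pooling == "varying":
        scalar_views["mu_alpha"] = draws["mu_alpha"]
        scalar_views["sigma_alpha"] = draws["sigma_alpha"]
    for j, col in enumerate(design.columns):
        scalar_views[f"beta[{col}]"] = draws["beta"][:, :, j]
    scalar_views["shape"] = draws["shape"]
    if design.initiator_column is not None:
        scalar_views["p_init"] = draws["p_init"]

    summaries: list[ParameterSummary] = []
    notes: list[str] = []
    converged = True
    for name, chains in scalar_views.items():
        rhat, ess = diagnostics(chains)
        lo, hi = hdi(chains.ravel())
        summaries.append(
            ParameterSummary(
                name=name, mean=float(chains.mean()),
                hdi_low=lo, hdi_high=hi, rhat=rhat, ess=ess,
            )
        )
        if rhat >= config.target_rhat:
            converged = False
            notes.append(f"{name}: R-hat {rhat:.3f} >= {config.target_rhat}")
        if ess < config.target_ess:
            notes.append(f"{name}: ESS {ess:.0f} below target {config.target_ess:.0f}")

    return PosteriorSummary(
        spec=spec, config=config, design=design, draws=draws,
        summaries=summaries, log_lik=log_lik,
        converged=converged, convergence_notes=notes,
    )


# ----------------------------------------------------------------------
# Derived posterior quantities


def _baseline_eta(post: PosteriorSummary) -> np.ndarray:
    """Per-draw linear predictor at reference covariates, grand-mean context."""
    if post.spec.context_pooling == "varying":
        return post.draws_flat("mu_alpha")
    return post.draws_flat("alpha").mean(axis=1)


def expected_severity_draws(post: PosteriorSummary, at: str = "reference") -> np.ndarray:
    """Per-draw expected severity at the grand-mean context intercept.

    ``at='reference'`` sets every covariate to its reference level and
    duration to the sample mean; ``at='mean'`` uses the average design
    row (dummy columns at their sample proportions), a plug-in estimate
    of the population-average expected severity.
    """
    eta = _baseline_eta(post)
    if at == "mean":
        xbar = post.design.X.mean(axis=0)
        eta = eta + post.draws_flat("beta") @ xbar
    elif at != "reference":
        raise ValueError("at must be 'reference' or 'mean'")
    return np.exp(eta)


def contrasts(
    post: PosteriorSummary,
    pairs: Iterable[tuple[str, str, str]],
    mass: float = 0.95,
) -> list[dict]:
    """Expected-severity differences between category levels.

    ``pairs`` is an iterable of (variable, level_1, level_2); each entry
    yields the posterior of ``E[y | level_1] - E[y | level_2]`` on the
    response scale, with every other predictor at its reference level,
    duration at the sample mean, and the context intercept at the grand
    mean.  A difference is flagged significant when its HDI excludes 0.
    """
    base = _baseline_eta(post)
    beta = post.draws_flat("beta")
    colindex = {c: j for j, c in enumerate(post.design.columns)}

    def level_eta(var: str, level: str) -> np.ndarray:
        if level == post.design.reference_levels.get(var):
            return base
        col = f"{var}[{level}]"
        if col not in colindex:
            raise ValueError(f"unknown level {level!r} for {var!r} in this fit")
        return base + beta[:, colindex[col]]

    results = []
    for var, l1, l2 in pairs:
        if var not in post.design.reference_levels:
            raise ValueError(f"{var!r} is not a fitted categorical predictor")
        diff = np.exp(level_eta(var, l1)) - np.exp(level_eta(var, l2))
        if l1 == l2:
            lo = hi = 0.0
        else:
            lo, hi = hdi(diff, mass)
        results.append(
            {
                "variable": var,
                "levels": (l1, l2),
                "mean": float(diff.mean()),
                "hdi_low": lo,
                "hdi_high": hi,
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return results


def icc(post: PosteriorSummary, mass: float = 0.95) -> dict:
    """Intra-class correlation: between-context share of total variance.

    On the log scale the residual variance of a gamma variate is
    trigamma(shape), so per draw
    ICC = sigma_alpha^2 / (sigma_alpha^2 + trigamma(shape)).
    Defined only for the varying-intercept model.
    """
    if post.spec.context_pooling != "varying":
        raise ValueError("ICC is undefined for a fixed-effect context fit")
    sigma = post.draws_flat("sigma_alpha")
    shape = post.draws_flat("shape")
    draws = sigma**2 / (sigma**2 + polygamma(1, shape))
    lo, hi = hdi(draws, mass)
    return {"mean": float(draws.mean()), "hdi_low": lo, "hdi_high": hi, "draws": draws}


def duration_effect(post: PosteriorSummary, mass: float = 0.95) -> dict:
    """Duration-of-interaction effect per one sample SD of duration.

    Two labelled summaries: ``multiplier`` is exp(beta), the
    multiplicative change in expected severity per SD; ``slope_points``
    is the response-scale difference mu(z+1) - mu(z) at the grand-mean
    baseline, in severity points per SD.
    """
    j = post.design.columns.index("duration_z")
    b = post.draws_flat("beta")[:, j]
    base = np.exp(_baseline_eta(post))
    multiplier = np.exp(b)
    slope = base * (np.exp(b) - 1.0)
    m_lo, m_hi = hdi(multiplier, mass)
    s_lo, s_hi = hdi(slope, mass)
    return {
        "sd_seconds": post.design.duration_sd_s,
        "multiplier": {"mean": float(multiplier.mean()), "hdi_low": m_lo, "hdi_high": m_hi},
        "slope_points": {"mean": float(slope.mean()), "hdi_low": s_lo, "hdi_high": s_hi},
    }
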