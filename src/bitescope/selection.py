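"""Candidate-model enumeration, WAIC and WAIC weights.

The baseline model contains the interaction contexts (varying
intercepts), interaction duration and dog size; candidate models add
every non-empty combination of the optional predictors (victim sex,
victim age, bite site, initiator), and the full model is additionally
recomputed with contexts as a fixed rather than a varying effect to
assess whether partial pooling is needed.  Models are compared on the
widely applicable information criterion (WAIC, deviance scale, lower is
better), transformed to Akaike-type weights that give each model's
relative probability of best out-of-sample predictive accuracy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .hier_model import MCMCConfig, ModelSpec, PosteriorSummary, fit

__all__ = [
    "WAICResult",
    "enumerate_models",
    "waic",
    "waic_weights",
    "rank_models",
    "fit_and_rank",
]

_OPTIONAL = ("victim_sex", "victim_age", "bite_site", "initiator")


@dataclass
class WAICResult:
    model: ModelSpec
    lppd: float
    p_waic: float
    waic: float
    weight: float | None = None
    delta: float | None = None
    n_obs: int | None = None


def enumerate_models(
    optional_predictors: Sequence[str] = _OPTIONAL,
    include_fixed_variant: bool = True,
) -> list[ModelSpec]:
    """Baseline plus all combinations of the optional predictors.

    With the default four optional predictors this yields the baseline
    and 2^4 - 1 = 15 augmented varying-context models, plus (when
    ``include_fixed_variant``) a fixed-context copy of the full model.
    A narrower comparison set can be obtained by passing a subset of
    predictors or by filtering the returned list.
    """
    unknown = set(optional_predictors) - set(_OPTIONAL)
    if unknown:
        raise ValueError(f"unknown optional predictor(s): {sorted(unknown)}")
    specs: list[ModelSpec] = []
    for r in range(len(optional_predictors) + 1):
        for combo in itertools.combinations(optional_predictors, r):
            specs.append(
                ModelSpec(**{f"include_{name}": name in combo for name in _OPTIONAL})
            )
    if include_fixed_variant and optional_predictors:
        full = specs[-1]
        specs.append(replace(full, context_pooling="fixed"))
    return specs


def waic(log_lik: np.ndarray, model: ModelSpec | None = None) -> WAICResult:
    """WAIC from a (draws x observations) pointwise log-likelihood matrix.

    lppd_i = log mean_s exp(ll_si) (log-sum-exp stabilised);
    p_waic_i = var_s(ll_si); waic = -2 (lppd - p_waic).
    """
    ll = np.asarray(log_lik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("log_lik must be a (draws >= 2, observations) matrix")
    bad = np.flatnonzero(~np.isfinite(ll).all(axis=0))
    if bad.size:
        raise ValueError(f"non-finite log-likelihoods at observation(s) {bad.tolist()}")
    S = ll.shape[0]
    m = ll.max(axis=0)
    lppd = float(np.sum(m + np.log(np.exp(ll - m).mean(axis=0))))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    return WAICResult(
        model=model, lppd=lppd, p_waic=p_waic,
        waic=-2.0 * (lppd - p_waic), n_obs=ll.shape[1],
    )


def waic_weights(results: Sequence[WAICResult]) -> list[WAICResult]:
    """Attach Akaike-type weights: w_m = exp(-delta_m/2) / sum_k exp(-delta_k/2)."""
    if not results:
        raise ValueError("results must be non-empty")
    waics = np.array([r.waic for r in results])
    delta = waics - waics.min()
    raw = np.exp(-0.5 * delta)
    weights = raw / raw.sum()
    for r, d, w in zip(results, delta, weights):
        r.delta = float(d)
        r.weight = float(w)
    return list(results)


def _n_predictors(spec: ModelSpec) -> int:
    return len(spec.optional_predictors)


def rank_models(fits: Sequence[PosteriorSummary]) -> list[WAICResult]:
    """Rank fitted models by WAIC (ascending); ties prefer fewer predictors.

    All fits must share the same observations.
    """
    if not fits:
        raise ValueError("fits must be non-empty")
    n_obs = {f.log_lik.shape[1] for f in fits}
    if len(n_obs) != 1:
        raise ValueError(f"fits cover differing observation counts: {sorted(n_obs)}")
    results = [waic(f.log_lik, model=f.spec) for f in fits]
    results = waic_weights(results)
    results.sort(key=lambda r: (r.waic, _n_predictors(r.model), r.model.name))
    return results


def fit_and_rank(records, specs=None, config: MCMCConfig = MCMCConfig()):
    """Fit every candidate model and return (fits, ranked WAIC table)."""
    if specs is None:
        specs = enumerate_models()
    fits = [fit(records, spec, config) for spec in specs]
    return fits, rank_models(fits)


def selection_table(results: Sequence[WAICResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": range(1, len(results) + 1),
            "spec": [r.model.name if r.model else "?" for r in results],
            "waic": [r.waic for r in results],
            "p_waic": [r.p_waic for r in results],
            "delta": [r.delta for r in results],
            "weight": [r.weight for r in results],
        }
    )
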