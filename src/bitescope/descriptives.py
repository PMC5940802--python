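"""Descriptive tables, bootstrap context means and observer reliability.

Covers the summary cross-tabulation of victim / dog / bite variables
against the eight interaction contexts, the non-parametric bootstrap
sample means of severity per context, and Cohen's kappa for intra- and
inter-rater agreement (0.61-0.80 treated as acceptable agreement).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import CONTEXTS, VideoRecord
from .severity import score_records

__all__ = [
    "ContextMeanCI",
    "KappaResult",
    "cross_tabulate",
    "bootstrap_context_means",
    "cohens_kappa",
    "kappa_band",
]

_CATEGORICAL_FIELDS = {
    "context", "dog_size", "dog_breed", "victim_age", "victim_sex",
    "bite_site", "initiator", "location", "handler_sex",
}


@dataclass(frozen=True)
class ContextMeanCI:
    """Sample mean severity and bootstrap percentile CI for one context."""

    context: str
    sample_mean: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    band: str


def cross_tabulate(records: Sequence[VideoRecord], row_variable: str) -> pd.DataFrame:
    """Within-level percentage distribution across the eight contexts.

    One row per level of ``row_variable``; cells are the percentage of
    that level's videos falling in each context (rows sum to 100), plus
    a ``total_n`` count column.
    """
    if row_variable not in _CATEGORICAL_FIELDS:
        raise ValueError(f"{row_variable!r} is not a categorical field")
    frame = pd.DataFrame(
        {
            "level": [getattr(r, row_variable) for r in records],
            "context": [r.context for r in records],
        }
    )
    counts = (
        frame.groupby(["level", "context"]).size().unstack(fill_value=0)
        .reindex(columns=CONTEXTS, fill_value=0)
    )
    totals = counts.sum(axis=1)
    percentages = counts.div(totals, axis=0) * 100.0
    percentages["total_n"] = totals
    percentages.index.name = row_variable
    return percentages


def bootstrap_context_means(
    records: Sequence[VideoRecord],
    B: int = 10_000,
    seed: int | None = None,
    scores: Mapping[str, float] | None = None,
) -> list[ContextMeanCI]:
    """Non-parametric bootstrap of the mean severity score per context.

    Videos are resampled with replacement within each context; the CI is
    the percentile 2.5/97.5 interval over ``B`` replicates.  Contexts
    with no videos are omitted.  Deterministic given ``seed``.
    """
    if scores is None:
        scores = {s.video_id: float(s.score) for s in score_records(records)}
    rng = np.random.default_rng(seed)
    out: list[ContextMeanCI] = []
    for context in CONTEXTS:
        values = np.array(
            [scores[r.video_id] for r in records if r.context == context], dtype=float
        )
        if values.size == 0:
            continue
        idx = rng.integers(0, values.size, size=(B, values.size))
        replicate_means = values[idx].mean(axis=1)
        low, high = np.percentile(replicate_means, [2.5, 97.5])
        out.append(
            ContextMeanCI(
                context=context,
                sample_mean=float(values.mean()),
                ci_low=float(low),
                ci_high=float(high),
                n=int(values.size),
            )
        )
    return out


def kappa_band(kappa: float) -> str:
    """Conventional agreement band; 0.61-0.80 is 'acceptable'."""
    if kappa <= 0.20:
        return "poor"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "acceptable"
    return "high"


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> KappaResult:
    """Unweighted Cohen's kappa between two raters' category labels.

    kappa = (po - pe) / (1 - pe) with po the observed agreement and pe
    the chance agreement from the raters' marginal label frequencies.
    Perfect agreement with degenerate marginals (pe = 1) is defined as
    kappa = 1.
    """
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("ratings must be non-empty")
    n = len(a)
    labels = sorted(set(a) | set(b), key=str)
    index = {lab: i for i, lab in enumerate(labels)}
    confusion = np.zeros((len(labels), len(labels)))
    for x, y in zip(a, b):
        confusion[index[x], index[y]] += 1
    confusion /= n
    po = float(np.trace(confusion))
    pe = float(confusion.sum(axis=1) @ confusion.sum(axis=0))
    if pe >= 1.0:
        kappa = 1.0 if po >= 1.0 else 0.0
    else:
        kappa = (po - pe) / (1 - pe)
    return KappaResult(
        kappa=float(kappa),
        observed_agreement=po,
        expected_agreement=pe,
        band=kappa_band(float(kappa)),
    )
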