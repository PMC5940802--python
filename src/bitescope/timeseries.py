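"""Scan-sampled behaviour time series aligned to the bite.

Behaviour coding marks, for every 3-second window from the start of the
human-dog interaction back from the first bite, whether each ethogram
code occurred.  This module aggregates those observations into a
per-offset proportion of videos showing the behaviour, smooths the
series with a 3-point moving average, and attaches Wilson 95%
confidence intervals — the computation behind the pre-bite behaviour
figures.

Offsets are window indices counted backwards from the bite (window 0 is
the 3 s ending at the bite).  The series is truncated at 35 s before
the bite, i.e. window index 11, because few interactions are coded
longer than that; window 11 covers (33, 36] s and is retained since
35 s falls inside it.  The denominator at each offset is the number of
videos still under observation ("at risk"): videos whose coded
interaction covers that window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .core_data import BehaviourObservation

__all__ = [
    "MAX_WINDOW_INDEX",
    "BehaviourSeries",
    "aggregate_proportions",
    "moving_average",
    "proportion_ci",
    "attach_ci_and_smoothing",
    "behaviour_series",
    "series_frame",
]

#: Largest retained window index; window 11 covers (33, 36] s pre-bite.
MAX_WINDOW_INDEX = 11


@dataclass
class BehaviourSeries:
    """Per-offset occurrence proportions for one behaviour code."""

    actor: str
    behaviour: str
    offsets: list[int]
    at_risk: list[int]
    counts: list[int]
    proportion: list[float]
    ci_low: list[float] = field(default_factory=list)
    ci_high: list[float] = field(default_factory=list)
    smoothed: list[float] = field(default_factory=list)


def aggregate_proportions(
    observations: Iterable[BehaviourObservation],
    video_lengths: Mapping[str, int],
    actor: str,
    behaviour: str,
    max_window: int = MAX_WINDOW_INDEX,
) -> BehaviourSeries:
    """Aggregate presence marks into per-offset proportions.

    ``video_lengths`` maps each video id to its number of coded windows;
    the at-risk denominator at offset ``w`` is the number of videos with
    length > w.  Offsets beyond ``max_window`` or with an empty at-risk
    set are omitted.  Combinations absent from ``observations`` count as
    not present.
    """
    present: dict[int, set[str]] = {}
    for obs in observations:
        if obs.actor != actor or obs.behaviour != behaviour:
            continue
        length = video_lengths.get(obs.video_id)
        if length is None:
            raise ValueError(f"no coded length for video {obs.video_id!r}")
        if obs.window_index >= length:
            raise ValueError(
                f"video {obs.video_id!r}: window {obs.window_index} beyond "
                f"coded length {length}"
            )
        if obs.present:
            present.setdefault(obs.window_index, set()).add(obs.video_id)

    offsets, at_risk, counts, proportion = [], [], [], []
    for w in range(max_window + 1):
        n = sum(1 for length in video_lengths.values() if length > w)
        if n == 0:
            continue
        k = len(present.get(w, ()))
        offsets.append(w)
        at_risk.append(n)
        counts.append(k)
        proportion.append(k / n)
    return BehaviourSeries(
        actor=actor, behaviour=behaviour, offsets=offsets,
        at_risk=at_risk, counts=counts, proportion=proportion,
    )


def moving_average(series: Sequence[float], window: int = 3) -> list[float]:
    """Centered moving average; ends use the truncated window."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    values = list(series)
    if not values:
        return []
    half = window // 2
    out = []
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out.append(sum(values[lo:hi]) / (hi - lo))
    return out


def proportion_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError(f"successes {successes} outside [0, {n}]")
    low, high = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return float(low), float(high)


def attach_ci_and_smoothing(series: BehaviourSeries, level: float = 0.95) -> BehaviourSeries:
    """Fill in Wilson CIs and the 3-point moving average in place."""
    bounds = [proportion_ci(k, n, level) for k, n in zip(series.counts, series.at_risk)]
    series.ci_low = [b[0] for b in bounds]
    series.ci_high = [b[1] for b in bounds]
    series.smoothed = moving_average(series.proportion)
    return series


def behaviour_series(
    observations: Iterable[BehaviourObservation],
    video_lengths: Mapping[str, int],
    actor: str,
    behaviour: str,
    level: float = 0.95,
    max_window: int = MAX_WINDOW_INDEX,
) -> BehaviourSeries:
    """Aggregate, then attach CIs and smoothing (one-call convenience)."""
    series = aggregate_proportions(
        list(observations), video_lengths, actor, behaviour, max_window
    )
    return attach_ci_and_smoothing(series, level)


def series_frame(series: BehaviourSeries) -> pd.DataFrame:
    """Tabular view: offset, seconds-before-bite, proportion, CI, smoothed."""
    return pd.DataFrame(
        {
            "actor": series.actor,
            "behaviour": series.behaviour,
            "offset": series.offsets,
            "seconds_before_bite": [3 * (w + 1) for w in series.offsets],
            "at_risk": series.at_risk,
            "count": series.counts,
            "proportion": series.proportion,
            "ci_low": series.ci_low,
            "ci_high": series.ci_high,
            "smoothed": series.smoothed,
        }
    )
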