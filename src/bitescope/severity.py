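"""Perceived bite-severity scoring.

Severity as perceived from video is the composite

    score = n * a + b + c

with ``n`` the number of bites to the victim observed in the video,
``a = 3`` when a puncture wound is visible (``a = 1`` otherwise — a
puncture is assumed absent when it cannot be ascertained), ``b = 1``
when the dog shook its head whilst biting, and ``c = 1`` when the dog
held on for more than one second.  When a video shows several bites of
different severity, the most extreme value of each component across the
bites enters the total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .core_data import VideoRecord

__all__ = ["SeverityScore", "BiteComponents", "score_video", "score_multibite", "score_records"]


class BiteComponents(NamedTuple):
    """Per-bite components: visible puncture, head shake, hold > 1 s."""

    puncture: bool
    shake: bool
    hold: bool


@dataclass(frozen=True)
class SeverityScore:
    video_id: str
    score: int
    n: int
    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if self.score != self.n * self.a + self.b + self.c:
            raise ValueError("score must equal n*a + b + c")
        if not (self.n <= self.score <= 3 * self.n + 2):
            raise ValueError(f"score {self.score} outside [n, 3n+2] for n={self.n}")


def score_video(
    n_bites: int,
    puncture_visible: bool,
    head_shake: bool,
    hold_gt_1s: bool,
    video_id: str = "",
) -> SeverityScore:
    """Score a video from its already-collapsed per-video components."""
    if n_bites < 1:
        raise ValueError(f"n_bites must be >= 1, got {n_bites}")
    a = 3 if puncture_visible else 1
    b = 1 if head_shake else 0
    c = 1 if hold_gt_1s else 0
    return SeverityScore(video_id=video_id, score=n_bites * a + b + c, n=n_bites, a=a, b=b, c=c)


def score_multibite(bites: Iterable[BiteComponents], video_id: str = "") -> SeverityScore:
    """Score a video from raw per-bite components.

    ``n`` is the number of bites; each of a, b, c takes its most
    extreme value across bites before entering the total.
    """
    bites = [BiteComponents(*b) for b in bites]
    if not bites:
        raise ValueError("bites must be non-empty")
    return score_video(
        n_bites=len(bites),
        puncture_visible=any(b.puncture for b in bites),
        head_shake=any(b.shake for b in bites),
        hold_gt_1s=any(b.hold for b in bites),
        video_id=video_id,
    )


def score_records(records: Iterable[VideoRecord]) -> list[SeverityScore]:
    """Score every coded video record."""
    return [
        score_video(
            r.n_bites, r.puncture_visible, r.head_shake, r.hold_gt_1s, video_id=r.video_id
        )
        for r in records
    ]
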