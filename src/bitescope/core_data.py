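"""Domain types, controlled vocabularies and delimited-text I/O.

The coded-video table has one row per video: the interaction context
(one of eight categories of interaction preceding the bite), the components of
the perceived bite-severity score, and victim / dog / setting covariates.
The behaviour table is long-format scan-sampling output: one row per
(video, actor, behaviour code, 3-second window before the bite).

Missing values are written as the literal token ``NA``; an empty cell is
accepted on input.  Time runs backwards from the bite: window ``w``
covers the half-open interval ``(3w, 3(w+1)]`` seconds before the first
bite, so ``w = 0`` is the 3 s ending at the bite.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd

__all__ = [
    "CONTEXTS",
    "DOG_SIZES",
    "VICTIM_AGES",
    "SEXES",
    "BITE_SITES",
    "INITIATORS",
    "LOCATIONS",
    "MISSING",
    "VideoRecord",
    "BehaviourObservation",
    "EthogramVocabulary",
    "DEFAULT_DOG_ETHOGRAM",
    "DEFAULT_HUMAN_ETHOGRAM",
    "ValidationError",
    "SchemaError",
    "read_video_table",
    "write_video_table",
    "read_behaviour_table",
    "write_behaviour_table",
    "write_results",
]

#: The eight interaction contexts, one assigned per video.
CONTEXTS = (
    "resources",
    "benign",
    "resting",
    "unpleasant",
    "painful",
    "territorial",
    "public_space",
    "play",
)

DOG_SIZES = ("small", "medium", "big")
VICTIM_AGES = ("infant", "child", "adult")
SEXES = ("male", "female")
BITE_SITES = ("limbs", "head_face", "other", "multiple")
LOCATIONS = ("indoor", "outdoor")

#: Sentinel for a permitted missing category (written as "NA" in CSV).
MISSING = "missing"

INITIATORS = ("dog", "victim", MISSING)
HANDLER_SEXES = ("male", "female", MISSING)


class ValidationError(ValueError):
    """A cell value violates the controlled vocabulary or an invariant."""


class SchemaError(ValueError):
    """The file header does not match the documented schema."""


@dataclass(frozen=True)
class VideoRecord:
    """One coded video: context, severity components and covariates."""

    video_id: str
    context: str
    n_bites: int
    puncture_visible: bool
    head_shake: bool
    hold_gt_1s: bool
    interaction_duration_s: float
    dog_size: str
    dog_breed: str
    victim_age: str
    victim_sex: str
    bite_site: str
    initiator: str
    location: str
    handler_sex: str = MISSING

    def __post_init__(self) -> None:
        checks = [
            ("context", self.context, CONTEXTS, False),
            ("dog_size", self.dog_size, DOG_SIZES, False),
            ("victim_age", self.victim_age, VICTIM_AGES, False),
            ("victim_sex", self.victim_sex, SEXES, False),
            ("bite_site", self.bite_site, BITE_SITES, False),
            ("initiator", self.initiator, INITIATORS, True),
            ("location", self.location, LOCATIONS, False),
            ("handler_sex", self.handler_sex, HANDLER_SEXES, True),
        ]
        for name, value, allowed, _ in checks:
            if value not in allowed:
                raise ValidationError(
                    f"{name}={value!r} is not one of {sorted(allowed)}"
                )
        if self.n_bites < 1:
            raise ValidationError(f"n_bites must be >= 1, got {self.n_bites}")
        if not self.interaction_duration_s > 0:
            raise ValidationError(
                f"interaction_duration_s must be > 0, got {self.interaction_duration_s}"
            )


@dataclass(frozen=True)
class BehaviourObservation:
    """Presence of one ethogram code in one 3-s window of one video."""

    video_id: str
    actor: str
    behaviour: str
    window_index: int
    present: bool

    def __post_init__(self) -> None:
        if self.actor not in ("dog", "human"):
            raise ValidationError(f"actor={self.actor!r} must be 'dog' or 'human'")
        if self.window_index < 0:
            raise ValidationError(
                f"window_index must be >= 0, got {self.window_index}"
            )


@dataclass(frozen=True)
class EthogramVocabulary:
    """Declared behaviour-code vocabulary for one actor."""

    actor: str
    codes: dict[str, str] = field(default_factory=dict)  # code -> definition

    def __post_init__(self) -> None:
        if self.actor not in ("dog", "human"):
            raise ValidationError(f"actor={self.actor!r} must be 'dog' or 'human'")

    def __contains__(self, code: str) -> bool:
        return code in self.codes


# Compact default ethograms covering the behaviour families coded in the
# study: displacement/appeasement signals, posture, vocalisation,
# locomotion and contact for dogs; macro-movements, tactile contact,
# vocalisation and position for humans.
DEFAULT_DOG_ETHOGRAM = EthogramVocabulary(
    actor="dog",
    codes={
        "body_awkward": "body held in an awkward, tense posture",
        "body_low": "body held in a low position",
        "ear_non_neutral": "ears pinned back or otherwise non-neutral",
        "head_turn": "head turned away from the person",
        "stare": "fixed stare at the person",
        "stiffen": "body stiffens / freezes",
        "frown": "facial tension, lips drawn",
        "snap": "snap without contact",
        "growl": "growling vocalisation",
        "pant": "panting",
        "lip_lick": "nose or lip licking",
        "paw_lift": "one forepaw raised",
        "yawn": "yawning outside rest context",
        "shake_off": "whole-body shake-off",
        "play_bow": "play bow",
        "gentle_contact": "gentle muzzle or paw contact with the person",
        "intensive_contact": "intensive (forceful) contact with the person",
    },
)

DEFAULT_HUMAN_ETHOGRAM = EthogramVocabulary(
    actor="human",
    codes={
        "stand_over": "standing or leaning over the dog",
        "move_toward": "moving limbs, body or object toward the dog",
        "move_away": "moving away from the dog",
        "pet": "petting the dog",
        "restrain": "restraining or holding the dog",
        "hug": "hugging the dog",
        "push_pull": "pushing or pulling the dog",
        "hit": "hitting the dog",
        "lift": "lifting the dog",
        "talk": "normal talking",
        "laugh": "laughing",
        "pain_vocal": "pain-related vocalisation",
        "crouch": "crouching near the dog",
    },
)

_BOOL_COLUMNS = ("puncture_visible", "head_shake", "hold_gt_1s")

VIDEO_COLUMNS = [f.name for f in dataclasses.fields(VideoRecord)]
BEHAVIOUR_COLUMNS = [f.name for f in dataclasses.fields(BehaviourObservation)]

_NA_TOKENS = ("NA", "")


def _parse_bool(value: Any, row: int, column: str) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValidationError(f"row {row}, column {column!r}: {value!r} is not a boolean")


def read_video_table(path: str | Path) -> list[VideoRecord]:
    """Read and validate a coded-video CSV into :class:`VideoRecord` rows.

    The token ``NA`` (or an empty cell) maps to ``missing`` where the
    schema permits it (``initiator`` and ``handler_sex``); a missing
    value anywhere else, or a category label outside the controlled
    vocabularies, raises :class:`ValidationError` naming the row and
    column.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(VIDEO_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise SchemaError(f"missing required column(s): {sorted(missing_cols)}")

    records: list[VideoRecord] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        raw = {col: getattr(row, col) for col in VIDEO_COLUMNS}
        kwargs: dict[str, Any] = {"video_id": str(raw["video_id"])}
        for col in ("initiator", "handler_sex"):
            value = str(raw[col]).strip()
            kwargs[col] = MISSING if value in _NA_TOKENS else value
        for col in (
            "context", "dog_size", "dog_breed", "victim_age",
            "victim_sex", "bite_site", "location",
        ):
            kwargs[col] = str(raw[col]).strip()
        try:
            kwargs["n_bites"] = int(raw["n_bites"])
            kwargs["interaction_duration_s"] = float(raw["interaction_duration_s"])
        except ValueError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        for col in _BOOL_COLUMNS:
            kwargs[col] = _parse_bool(raw[col], i, col)
        try:
            records.append(VideoRecord(**kwargs))
        except ValidationError as exc:
            raise ValidationError(f"row {i} ({raw['video_id']}): {exc}") from exc
    return records


def write_video_table(records: Iterable[VideoRecord], path: str | Path) -> None:
    """Write video records back to CSV, using ``NA`` for missing."""
    rows = []
    for rec in records:
        row = dataclasses.asdict(rec)
        for col in ("initiator", "handler_sex"):
            if row[col] == MISSING:
                row[col] = "NA"
        rows.append(row)
    pd.DataFrame(rows, columns=VIDEO_COLUMNS).to_csv(path, index=False)


def read_behaviour_table(
    path: str | Path,
    vocab: Sequence[EthogramVocabulary] = (DEFAULT_DOG_ETHOGRAM, DEFAULT_HUMAN_ETHOGRAM),
) -> list[BehaviourObservation]:
    """Read a long-format behaviour-coding CSV.

    Every behaviour code must belong to the declared ethogram for its
    actor.  Absent (video, window, behaviour) combinations are
    interpreted as ``present=False`` by downstream consumers, so a
    sparse table listing only positive windows is valid.
    """
    by_actor = {v.actor: v for v in vocab}
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(BEHAVIOUR_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise SchemaError(f"missing required column(s): {sorted(missing_cols)}")

    observations: list[BehaviourObservation] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        actor = str(row.actor).strip()
        behaviour = str(row.behaviour).strip()
        if actor not in by_actor:
            raise ValidationError(f"row {i}: unknown actor {actor!r}")
        if behaviour not in by_actor[actor]:
            raise ValidationError(
                f"row {i}: behaviour {behaviour!r} not in the {actor} ethogram"
            )
        try:
            window = int(row.window_index)
        except ValueError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        observations.append(
            BehaviourObservation(
                video_id=str(row.video_id),
                actor=actor,
                behaviour=behaviour,
                window_index=window,
                present=_parse_bool(row.present, i, "present"),
            )
        )
    return observations


def write_behaviour_table(
    observations: Iterable[BehaviourObservation], path: str | Path
) -> None:
    rows = [dataclasses.asdict(o) for o in observations]
    pd.DataFrame(rows, columns=BEHAVIOUR_COLUMNS).to_csv(path, index=False)


def write_results(obj: Any, path: str | Path) -> None:
    """Persist a result object: JSON for summaries, CSV for tables.

    DataFrames and lists of dataclasses go to CSV when the path ends in
    ``.csv``; anything else is serialised as JSON (dataclasses are
    converted to dicts first).  Round-trips of numeric fields are
    lossless at double precision.
    """
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
        return
    if path.suffix.lower() == ".csv":
        if isinstance(obj, (list, tuple)):
            rows = [
                dataclasses.asdict(o) if dataclasses.is_dataclass(o) else dict(o)
                for o in obj
            ]
            pd.DataFrame(rows).to_csv(path, index=False)
        else:
            raise TypeError(f"cannot write {type(obj).__name__} as CSV")
        return

    def _default(o: Any) -> Any:
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if hasattr(o, "tolist"):
            return o.tolist()
        if hasattr(o, "item"):
            return o.item()
        raise TypeError(f"not JSON serialisable: {type(o).__name__}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
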