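"""Valence-based affective reward computation.

Facial-expression classifiers emit one of seven basic emotion labels per
video frame.  Each label carries a fixed signed valence score; the reward for
an interaction turn is the mean valence over all frames observed during that
turn, and the learning signal is the change in reward between consecutive
turns (a non-negative change counts as a success for the style that was
played).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union


class EmotionParseError(ValueError):
    """Raised when a string cannot be interpreted as one of the 7 emotions."""


class ValenceConfigError(ValueError):
    """Raised when a valence-map configuration is incomplete or out of range."""


class EmptyTurnError(ValueError):
    """Raised in strict mode when a turn contains no emotion frames."""


class EmotionLabel(enum.Enum):
    """The seven basic emotion categories recognised by the classifier."""

    HAPPY = "Happy"
    SURPRISE = "Surprise"
    NEUTRAL = "Neutral"
    ANGRY = "Angry"
    DISGUST = "Disgust"
    SAD = "Sad"
    FEAR = "Fear"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical label ordering used for vectorised emission distributions.
LABELS: tuple[EmotionLabel, ...] = tuple(EmotionLabel)

# Several instruments name the same categories differently ("Happiness" vs
# "Happy"); both spellings are accepted, case-insensitively.
_ALIASES: dict[str, EmotionLabel] = {
    "happiness": EmotionLabel.HAPPY,
    "sadness": EmotionLabel.SAD,
    "anger": EmotionLabel.ANGRY,
}
_CANONICAL: dict[str, EmotionLabel] = {lab.value.lower(): lab for lab in LABELS}


def parse_emotion(text: str) -> EmotionLabel:
    """Parse an emotion name (case-insensitive, common synonyms accepted)."""
    if isinstance(text, EmotionLabel):
        return text
    key = str(text).strip().lower()
    label = _CANONICAL.get(key) or _ALIASES.get(key)
    if label is None:
        raise EmotionParseError(
            f"unknown emotion label {text!r}; expected one of "
            f"{[lab.value for lab in LABELS]} (or Happiness/Sadness/Anger)"
        )
    return label


@dataclass(frozen=True)
class ValenceMap:
    """Total mapping from emotion label to a valence score in [-1, +1]."""

    entries: Mapping[EmotionLabel, float]

    def __post_init__(self) -> None:
        missing = [lab.value for lab in LABELS if lab not in self.entries]
        if missing:
            raise ValenceConfigError(f"valence map missing labels: {missing}")
        for lab, v in self.entries.items():
            if not -1.0 <= float(v) <= 1.0:
                raise ValenceConfigError(
                    f"valence for {lab.value} is {v}, outside [-1, +1]"
                )
        object.__setattr__(self, "entries", dict(self.entries))

    @classmethod
    def from_dict(cls, scores: Mapping[str, float]) -> "ValenceMap":
        return cls({parse_emotion(k): float(v) for k, v in scores.items()})

    def __call__(self, label: EmotionLabel) -> float:
        return self.entries[label]

    @property
    def vmin(self) -> float:
        return min(self.entries.values())

    @property
    def vmax(self) -> float:
        return max(self.entries.values())

    def as_array(self) -> "list[float]":
        """Scores in canonical ``LABELS`` order."""
        return [self.entries[lab] for lab in LABELS]


#: Default per-emotion valence calibration.
DEFAULT_VALENCE = ValenceMap(
    {
        EmotionLabel.HAPPY: +0.76,
        EmotionLabel.SURPRISE: +0.40,
        EmotionLabel.NEUTRAL: 0.00,
        EmotionLabel.ANGRY: -0.43,
        EmotionLabel.DISGUST: -0.60,
        EmotionLabel.SAD: -0.63,
        EmotionLabel.FEAR: -0.64,
    }
)


@dataclass(frozen=True)
class EmotionObservation:
    """One classified video frame within a turn."""

    frame_index: int
    label: EmotionLabel

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be >= 0, got {self.frame_index}")


@dataclass(frozen=True)
class TurnReward:
    """Mean valence of the frames observed during one interaction turn."""

    turn_index: int
    reward: float
    frame_count: int

    def __post_init__(self) -> None:
        if self.turn_index < 1:
            raise ValueError("turn_index must be >= 1")
        if self.frame_count < 1:
            raise ValueError("frame_count must be >= 1")


def observations_from_labels(
    labels: Iterable[Union[EmotionLabel, str]]
) -> list[EmotionObservation]:
    """Wrap a plain label sequence as observations with frame indices 0..T-1."""
    return [
        EmotionObservation(i, parse_emotion(lab)) for i, lab in enumerate(labels)
    ]


def valence_of(
    label: Union[EmotionLabel, str], valence_map: ValenceMap = DEFAULT_VALENCE
) -> float:
    """Look up the valence score of a single emotion label."""
    return valence_map(parse_emotion(label))


def compute_turn_reward(
    frames: Sequence[EmotionObservation],
    valence_map: ValenceMap = DEFAULT_VALENCE,
    turn_index: int = 1,
) -> TurnReward:
    """Average the valence of a turn's frames into a single scalar reward.

    R = (1/T) * sum_t V(e_t) over the T frames of the turn.

    Raises
    ------
    EmptyTurnError
        If ``frames`` is empty (no face detected during the turn).
    ValueError
        If two frames share the same frame index.
    """
    if len(frames) == 0:
        raise EmptyTurnError(f"turn {turn_index} contains no emotion frames")
    indices = [f.frame_index for f in frames]
    if len(set(indices)) != len(indices):
        raise ValueError(f"duplicate frame indices within turn {turn_index}")
    entries = valence_map.entries
    total = sum(entries[f.label] for f in frames)
    return TurnReward(
        turn_index=turn_index, reward=total / len(frames), frame_count=len(frames)
    )


def compute_delta(current: TurnReward, previous: TurnReward) -> float:
    """Change in mean valence between two consecutive turns (Delta R).

    Raises ``ValueError`` unless ``current`` immediately follows ``previous``.
    """
    if current.turn_index != previous.turn_index + 1:
        raise ValueError(
            f"turns must be consecutive: got {previous.turn_index} -> "
            f"{current.turn_index}"
        )
    return current.reward - previous.reward


def is_success(delta: float) -> bool:
    """Non-negative valence change counts as a success for the played style."""
    return delta >= 0.0


# ---------------------------------------------------------------------------
# Emotion-stream CSV dialect: header ``turn,frame,emotion``; one row per
# frame; turns numbered from 1, frames from 0.
# ---------------------------------------------------------------------------

_STREAM_HEADER = ["turn", "frame", "emotion"]


def read_emotion_stream(path: Union[str, Path]) -> dict[int, list[EmotionObservation]]:
    """Read a per-frame emotion CSV into ``{turn: [observations]}``."""
    streams: dict[int, list[EmotionObservation]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            f.strip().lower() for f in reader.fieldnames
        ] != _STREAM_HEADER:
            raise EmotionParseError(
                f"emotion stream {path} must have header 'turn,frame,emotion', "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            turn = int(row["turn"])
            if turn < 1:
                raise EmotionParseError(f"turn numbers start at 1, got {turn}")
            obs = EmotionObservation(int(row["frame"]), parse_emotion(row["emotion"]))
            streams.setdefault(turn, []).append(obs)
    return streams


def write_emotion_stream(
    streams: Mapping[int, Sequence[EmotionObservation]], path: Union[str, Path]
) -> None:
    """Write ``{turn: [observations]}`` in the emotion-stream CSV dialect."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_STREAM_HEADER)
        for turn in sorted(streams):
            for obs in streams[turn]:
                writer.writerow([turn, obs.frame_index, obs.label.value])
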