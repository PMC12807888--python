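"""Synthetic affective users.

The study's participants are stood in for by generative profiles: each
simulated user emits, per interaction turn, a stream of i.i.d. categorical
emotion-frame labels whose distribution depends on the communicative style
being delivered.  A scalar personality trait (on the 0-32 scale of the EPQ
Psychoticism dimension, for interpretability) shifts which style yields the
higher expected valence, through a monotone logistic link: higher trait
values give the *neutral* style a larger expected-valence advantage.

Emission distributions are convex mixtures of two fixed anchor
distributions — one positive-leaning, one negative-leaning — so that the
expected valence of a style is linear in its mixture weight and available in
closed form as an oracle for the sampled streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .reward import (
    DEFAULT_VALENCE,
    LABELS,
    EmotionLabel,
    EmotionObservation,
    ValenceMap,
)
from .policy import DEFAULT_STYLE_NAMES, StyleId


class SimulatorConfigError(ValueError):
    """Raised for invalid cohort or profile parameters."""


class StreamExhaustedError(RuntimeError):
    """Raised when a recorded emotion stream runs out before the session ends."""


# Anchor distributions over LABELS order
# (Happy, Surprise, Neutral, Angry, Disgust, Sad, Fear).
POSITIVE_ANCHOR = np.array([0.55, 0.20, 0.25, 0.0, 0.0, 0.0, 0.0])
NEGATIVE_ANCHOR = np.array([0.0, 0.0, 0.25, 0.20, 0.10, 0.30, 0.15])

_SIMPLEX_TOL = 1e-9


@dataclass
class UserProfile:
    """A synthetic user: trait scalar plus per-style emission distributions."""

    user_id: str
    trait: float
    emission: Mapping[str, np.ndarray]
    preference_strength: float = 0.0
    noise_level: float = 0.0

    def __post_init__(self) -> None:
        if self.preference_strength < 0 or self.noise_level < 0:
            raise SimulatorConfigError(
                "preference_strength and noise_level must be >= 0"
            )
        emission = {}
        for name, probs in self.emission.items():
            p = np.asarray(probs, dtype=float)
            if p.shape != (len(LABELS),):
                raise SimulatorConfigError(
                    f"emission for style {name!r} must have {len(LABELS)} "
                    f"entries, got shape {p.shape}"
                )
            if np.any(p < 0) or abs(p.sum() - 1.0) > _SIMPLEX_TOL:
                raise SimulatorConfigError(
                    f"emission for style {name!r} is not a probability "
                    f"distribution (sum {p.sum()!r})"
                )
            emission[name] = p
        self.emission = emission


def expected_valence(
    profile: UserProfile,
    style: Union[StyleId, str],
    valence_map: ValenceMap = DEFAULT_VALENCE,
) -> float:
    """Closed-form expected frame valence of a style: sum_e pi(e) V(e)."""
    name = style.name if isinstance(style, StyleId) else style
    return float(np.dot(profile.emission[name], valence_map.as_array()))


def emit_turn_frames(
    profile: UserProfile,
    style: Union[StyleId, str],
    n_frames: int,
    rng: np.random.Generator,
) -> list[EmotionObservation]:
    """Draw one turn's frame labels i.i.d. from the style's emission."""
    if n_frames < 1:
        raise SimulatorConfigError(f"n_frames must be >= 1, got {n_frames}")
    name = style.name if isinstance(style, StyleId) else style
    cdf = np.cumsum(profile.emission[name])
    idx = np.searchsorted(cdf, rng.random(n_frames), side="right")
    idx = np.minimum(idx, len(LABELS) - 1)  # guard fp edge at u ~= 1
    return [EmotionObservation(i, LABELS[j]) for i, j in enumerate(idx)]


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a simulated participant cohort.

    Traits are drawn from a normal distribution truncated to the 0-32 scale.
    The trait-to-preference link is logistic in the standardised trait:
    ``gap = preference_strength * (2*sigmoid(slope*z + intercept) - 1)``,
    giving the neutral style a mixture-weight advantage of ``gap`` over the
    enthusiastic style, strictly increasing in the trait.
    """

    n_users: int = 10
    trait_mean: float = 16.0
    trait_sd: float = 6.0
    link_slope: float = 1.5
    link_intercept: float = 0.0
    preference_strength: float = 0.6
    noise_level: float = 0.1
    base_positivity: float = 0.5
    style_names: Sequence[str] = DEFAULT_STYLE_NAMES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise SimulatorConfigError(f"n_users must be >= 1, got {self.n_users}")
        if self.trait_sd <= 0:
            raise SimulatorConfigError("trait_sd must be > 0")
        if not 0.0 <= self.noise_level <= 1.0:
            raise SimulatorConfigError("noise_level must be in [0, 1]")
        if len(self.style_names) != 2:
            raise SimulatorConfigError(
                "the trait link is defined for exactly two styles"
            )
        lo = self.base_positivity - self.preference_strength / 2
        hi = self.base_positivity + self.preference_strength / 2
        if lo < 0.0 or hi > 1.0:
            raise SimulatorConfigError(
                "base_positivity +/- preference_strength/2 must stay in [0, 1]"
            )


def make_profile(spec: CohortSpec, user_id: str, trait: float) -> UserProfile:
    """Build one user's per-style emissions from the cohort's trait link."""
    z = (trait - spec.trait_mean) / spec.trait_sd
    gap = spec.preference_strength * (
        2.0 * _sigmoid(spec.link_slope * z + spec.link_intercept) - 1.0
    )
    neutral_name, enthusiastic_name = spec.style_names
    weights = {
        neutral_name: spec.base_positivity + gap / 2.0,
        enthusiastic_name: spec.base_positivity - gap / 2.0,
    }
    uniform = np.full(len(LABELS), 1.0 / len(LABELS))
    emission = {}
    for name, m in weights.items():
        mix = m * POSITIVE_ANCHOR + (1.0 - m) * NEGATIVE_ANCHOR
        emission[name] = (1.0 - spec.noise_level) * mix + spec.noise_level * uniform
    return UserProfile(
        user_id=user_id,
        trait=float(trait),
        emission=emission,
        preference_strength=spec.preference_strength,
        noise_level=spec.noise_level,
    )


def make_cohort(spec: CohortSpec) -> list[UserProfile]:
    """Draw ``spec.n_users`` profiles with truncated-normal traits."""
    rng = np.random.default_rng(spec.seed)
    traits = np.clip(
        rng.normal(spec.trait_mean, spec.trait_sd, spec.n_users), 0.0, 32.0
    )
    width = len(str(spec.n_users))
    return [
        make_profile(spec, f"u{str(i + 1).zfill(width)}", t)
        for i, t in enumerate(traits)
    ]


# ---------------------------------------------------------------------------
# Session-facing user objects.  All expose
#   frames_for_turn(turn_index, style, n_frames, rng) -> [EmotionObservation]
# ---------------------------------------------------------------------------


class SimulatedUser:
    """Session adapter around a :class:`UserProfile`."""

    def __init__(self, profile: UserProfile):
        self.profile = profile
        self.user_id = profile.user_id

    def frames_for_turn(
        self,
        turn_index: int,
        style: StyleId,
        n_frames: int,
        rng: np.random.Generator,
    ) -> list[EmotionObservation]:
        return emit_turn_frames(self.profile, style, n_frames, rng)


class StreamUser:
    """Replays a recorded per-turn emotion stream (e.g. from CSV)."""

    def __init__(
        self,
        streams: Mapping[int, Sequence[EmotionObservation]],
        user_id: str = "stream",
    ):
        self.streams = dict(streams)
        self.user_id = user_id

    def frames_for_turn(
        self,
        turn_index: int,
        style: StyleId,
        n_frames: int,
        rng: np.random.Generator,
    ) -> list[EmotionObservation]:
        try:
            return list(self.streams[turn_index])
        except KeyError:
            raise StreamExhaustedError(
                f"recorded emotion stream has no frames for turn {turn_index}"
            ) from None


class DeltaBernoulliUser:
    """A user whose affect dynamics give each style a fixed success rate.

    Ground-truth testbed for the bandit: at each turn the played style
    succeeds with its configured probability, and the user emits a frame
    composition (Happy vs Fear counts) whose mean valence realises that
    outcome under the delta-reward rule — a success re-pegs the reward at
    the top of the valence ladder, a failure steps one ladder rung below the
    previous reward.  With T frames per turn the construction is exact
    unless T consecutive failures occur (probability (1-p)^T per episode),
    in which case the reward floors and the drawn failure registers as a
    zero-delta success.
    """

    def __init__(self, success_probs: Sequence[float], user_id: str = "bernoulli"):
        probs = [float(p) for p in success_probs]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise SimulatorConfigError(
                f"success probabilities must be in [0, 1], got {probs}"
            )
        self.success_probs = probs
        self.user_id = user_id
        self._level: Optional[int] = None  # count of Happy frames last turn

    def frames_for_turn(
        self,
        turn_index: int,
        style: StyleId,
        n_frames: int,
        rng: np.random.Generator,
    ) -> list[EmotionObservation]:
        if style.index >= len(self.success_probs):
            raise SimulatorConfigError(
                f"no success probability configured for style {style.name!r}"
            )
        if self._level is None:
            level = n_frames // 2
        elif rng.random() < self.success_probs[style.index]:
            level = n_frames  # reward jumps to the ladder top: delta >= 0
        else:
            level = max(self._level - 1, 0)  # strictly lower unless floored
        self._level = level
        labels = [EmotionLabel.HAPPY] * level + [EmotionLabel.FEAR] * (
            n_frames - level
        )
        return [EmotionObservation(i, lab) for i, lab in enumerate(labels)]


# ---------------------------------------------------------------------------
# Cohort JSON round-trip.
# ---------------------------------------------------------------------------


def write_cohort(cohort: Sequence[UserProfile], path: Union[str, Path]) -> None:
    payload = [
        {
            "user_id": p.user_id,
            "trait": p.trait,
            "preference_strength": p.preference_strength,
            "noise_level": p.noise_level,
            "emission": {name: list(map(float, v)) for name, v in p.emission.items()},
        }
        for p in cohort
    ]
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_cohort(path: Union[str, Path]) -> list[UserProfile]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        UserProfile(
            user_id=e["user_id"],
            trait=float(e["trait"]),
            emission={k: np.asarray(v) for k, v in e["emission"].items()},
            preference_strength=float(e.get("preference_strength", 0.0)),
            noise_level=float(e.get("noise_level", 0.0)),
        )
        for e in payload
    ]
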