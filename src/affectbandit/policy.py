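"""Beta-Bernoulli Thompson Sampling over communicative styles.

Each style (arm) i keeps a Beta(alpha_i, beta_i) posterior over its
probability of producing a successful turn, where a turn is a success when
the mean facial valence did not drop relative to the previous turn.  Styles
start from uniform priors alpha_i = beta_i = 1.  At each turn a value
theta_i ~ Beta(alpha_i, beta_i) is sampled per arm and the argmax arm is
played; the played arm's alpha (success) or beta (failure) is incremented by
one once the next reward is observed.  No update is applied at the first
turn, where no previous reward exists.

Epsilon-greedy, UCB1 and uniform-random selection are provided as baselines
for benchmarking the Thompson policy; they share the same success/failure
bookkeeping.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np


class PolicyConfigError(ValueError):
    """Raised for invalid arm counts, priors or baseline parameters."""


#: Default style names, in arm-index order.
DEFAULT_STYLE_NAMES: tuple[str, ...] = ("neutral", "enthusiastic")


@dataclass(frozen=True)
class StyleId:
    """A communicative style, identified by contiguous arm index and name."""

    index: int
    name: str


@dataclass
class ArmState:
    """Beta posterior parameters of one style, with its priors retained.

    ``alpha - prior_alpha`` and ``beta - prior_beta`` are the observed
    success and failure counts.
    """

    alpha: float
    beta: float
    prior_alpha: float
    prior_beta: float

    @property
    def successes(self) -> float:
        return self.alpha - self.prior_alpha

    @property
    def failures(self) -> float:
        return self.beta - self.prior_beta

    @property
    def plays(self) -> float:
        return self.successes + self.failures


def posterior_mean(arm: ArmState) -> float:
    """Posterior mean success probability alpha / (alpha + beta)."""
    return arm.alpha / (arm.alpha + arm.beta)


@dataclass
class PolicyState:
    """Full bandit state: arms, turn counter, last reward and seeded RNG."""

    styles: list[StyleId]
    arms: list[ArmState]
    rng: np.random.Generator
    seed: Optional[int] = None
    turn_counter: int = 0
    last_reward: Optional[float] = None

    def arm_of(self, style: Union[StyleId, int, str]) -> ArmState:
        return self.arms[self._index_of(style)]

    def _index_of(self, style: Union[StyleId, int, str]) -> int:
        if isinstance(style, StyleId):
            return style.index
        if isinstance(style, int):
            return style
        for s in self.styles:
            if s.name == style:
                return s.index
        raise KeyError(f"unknown style {style!r}")


def init_policy(
    n_styles: int = 2,
    priors: Optional[Sequence[tuple[float, float]]] = None,
    names: Optional[Sequence[str]] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> PolicyState:
    """Create a policy with ``n_styles`` arms at (or above) uniform priors.

    Priors default to (1, 1) per arm; real-valued priors >= 1 are accepted
    for sensitivity experiments.
    """
    if n_styles < 1:
        raise PolicyConfigError(f"n_styles must be >= 1, got {n_styles}")
    if priors is None:
        priors = [(1.0, 1.0)] * n_styles
    if len(priors) != n_styles:
        raise PolicyConfigError(
            f"got {len(priors)} prior pairs for {n_styles} styles"
        )
    for a, b in priors:
        if a < 1.0 or b < 1.0:
            raise PolicyConfigError(f"priors must be >= 1, got ({a}, {b})")
    if names is None:
        if n_styles <= len(DEFAULT_STYLE_NAMES):
            names = DEFAULT_STYLE_NAMES[:n_styles]
        else:
            names = [f"style{i}" for i in range(n_styles)]
    if len(set(names)) != n_styles:
        raise PolicyConfigError(f"style names must be unique, got {names}")
    if rng is None:
        rng = np.random.default_rng(seed)
    styles = [StyleId(i, str(names[i])) for i in range(n_styles)]
    arms = [
        ArmState(alpha=float(a), beta=float(b), prior_alpha=float(a), prior_beta=float(b))
        for a, b in priors
    ]
    return PolicyState(styles=styles, arms=arms, rng=rng, seed=seed)


def sample_and_select(state: PolicyState) -> tuple[StyleId, np.ndarray]:
    """Thompson step: sample theta_i per arm and play the argmax.

    Samples are drawn in fixed arm-index order from the state's seeded
    generator, so identical states yield identical draws.  Floating-point
    ties break toward the lowest arm index.  Advances the turn counter.
    """
    thetas = np.array(
        [state.rng.beta(arm.alpha, arm.beta) for arm in state.arms]
    )
    chosen = int(np.argmax(thetas))
    state.turn_counter += 1
    return state.styles[chosen], thetas


def update_from_delta(
    state: PolicyState, played: Union[StyleId, int, str], delta: float
) -> PolicyState:
    """Credit the played arm with a success (delta >= 0) or failure.

    No update is applicable at the first turn (no previous reward exists);
    such a request is a warned no-op rather than an error so that callers
    replaying logs need not special-case the boundary.
    """
    if state.turn_counter < 2:
        warnings.warn(
            "bandit update requested at turn 1 (no previous reward); ignored",
            stacklevel=2,
        )
        return state
    arm = state.arm_of(played)
    if delta >= 0.0:
        arm.alpha += 1.0
    else:
        arm.beta += 1.0
    return state


def baseline_select(
    state: PolicyState,
    method: str,
    epsilon: float = 0.1,
    c: float = 2.0,
) -> StyleId:
    """Non-Bayesian reference policies sharing the arm bookkeeping.

    ``epsilon_greedy``
        With probability 1 - epsilon play the arm with the highest empirical
        success rate (unplayed arms count as rate 0), otherwise uniform.
    ``ucb``
        UCB1: argmax of rate + c * sqrt(ln(total plays) / arm plays);
        unplayed arms are played first, lowest index first.
    ``uniform``
        Equiprobable random arm.

    All methods advance the turn counter, like ``sample_and_select``.
    """
    n = len(state.arms)
    if method == "uniform":
        chosen = int(state.rng.integers(n))
    elif method == "epsilon_greedy":
        if not 0.0 <= epsilon <= 1.0:
            raise PolicyConfigError(f"epsilon must be in [0, 1], got {epsilon}")
        if state.rng.random() < epsilon:
            chosen = int(state.rng.integers(n))
        else:
            rates = [
                arm.successes / arm.plays if arm.plays > 0 else 0.0
                for arm in state.arms
            ]
            chosen = int(np.argmax(rates))
    elif method == "ucb":
        if c <= 0:
            raise PolicyConfigError(f"UCB exploration constant must be > 0, got {c}")
        unplayed = [i for i, arm in enumerate(state.arms) if arm.plays == 0]
        if unplayed:
            chosen = unplayed[0]
        else:
            total = sum(arm.plays for arm in state.arms)
            scores = [
                arm.successes / arm.plays + c * np.sqrt(np.log(total) / arm.plays)
                for arm in state.arms
            ]
            chosen = int(np.argmax(scores))
    else:
        raise PolicyConfigError(
            f"unknown baseline method {method!r}; expected "
            "'epsilon_greedy', 'ucb' or 'uniform'"
        )
    state.turn_counter += 1
    return state.styles[chosen]


# ---------------------------------------------------------------------------
# JSON serialisation.  The RNG bit-generator state is included so that a
# round-tripped policy resumes its draw stream exactly.
# ---------------------------------------------------------------------------


def policy_to_json(state: PolicyState) -> dict:
    return {
        "arms": [
            {
                "name": style.name,
                "alpha": arm.alpha,
                "beta": arm.beta,
                "prior_alpha": arm.prior_alpha,
                "prior_beta": arm.prior_beta,
            }
            for style, arm in zip(state.styles, state.arms)
        ],
        "turn": state.turn_counter,
        "last_reward": state.last_reward,
        "seed": state.seed,
        "rng_state": state.rng.bit_generator.state,
    }


def policy_from_json(payload: dict) -> PolicyState:
    arms_spec = payload["arms"]
    styles = [StyleId(i, a["name"]) for i, a in enumerate(arms_spec)]
    arms = [
        ArmState(
            alpha=float(a["alpha"]),
            beta=float(a["beta"]),
            prior_alpha=float(a.get("prior_alpha", 1.0)),
            prior_beta=float(a.get("prior_beta", 1.0)),
        )
        for a in arms_spec
    ]
    rng = np.random.default_rng(payload.get("seed"))
    if payload.get("rng_state") is not None:
        rng.bit_generator.state = payload["rng_state"]
    return PolicyState(
        styles=styles,
        arms=arms,
        rng=rng,
        seed=payload.get("seed"),
        turn_counter=int(payload.get("turn", 0)),
        last_reward=payload.get("last_reward"),
    )


def save_policy(state: PolicyState, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(policy_to_json(state)), encoding="utf-8")


def load_policy(path: Union[str, Path]) -> PolicyState:
    return policy_from_json(json.loads(Path(path).read_text(encoding="utf-8")))
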