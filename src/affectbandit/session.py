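"""End-to-end adaptive interaction sessions.

One session walks an ordered script under the selection/update loop: sample
a communicative style from the bandit, deliver the item, observe the turn's
emotion frames, average them into the valence reward, and — from the second
turn onward — credit the played style with a success (reward did not drop)
or a failure (reward dropped).  Everything is logged per turn so sessions
can be replayed and audited exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .policy import (
    DEFAULT_STYLE_NAMES,
    PolicyConfigError,
    PolicyState,
    baseline_select,
    init_policy,
    sample_and_select,
    update_from_delta,
)
from .reward import (
    DEFAULT_VALENCE,
    EmptyTurnError,
    TurnReward,
    ValenceMap,
    compute_delta,
    compute_turn_reward,
)
from .script import ScriptItem, make_default_script
from .users import SimulatedUser, UserProfile

#: Returned by :func:`classify_dominant_style` when no style clearly leads.
NO_CLEAR_PREFERENCE = "no clear preference"

_POLICY_KINDS = ("thompson", "epsilon_greedy", "ucb", "uniform")


@dataclass(frozen=True)
class SessionConfig:
    """Run configuration for one adaptive session."""

    n_turns: int = 32
    frames_per_turn: int = 30
    policy: str = "thompson"
    epsilon: float = 0.1
    ucb_c: float = 2.0
    priors: Optional[Sequence[tuple[float, float]]] = None
    style_names: Sequence[str] = DEFAULT_STYLE_NAMES
    seed: int = 0
    lenient_empty_turns: bool = False
    log_frames: bool = True
    dominance_margin: float = 2.0
    valence_scores: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.n_turns < 1:
            raise ValueError(f"n_turns must be >= 1, got {self.n_turns}")
        if self.frames_per_turn < 1:
            raise ValueError(
                f"frames_per_turn must be >= 1, got {self.frames_per_turn}"
            )
        if self.policy not in _POLICY_KINDS:
            raise PolicyConfigError(
                f"unknown policy {self.policy!r}; expected one of {_POLICY_KINDS}"
            )

    @property
    def valence_map(self) -> ValenceMap:
        if self.valence_scores is None:
            return DEFAULT_VALENCE
        return ValenceMap.from_dict(self.valence_scores)

    @classmethod
    def from_mapping(cls, payload: Mapping) -> "SessionConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown session config keys: {sorted(unknown)}")
        kwargs = dict(payload)
        if kwargs.get("priors") is not None:
            kwargs["priors"] = [tuple(map(float, p)) for p in kwargs["priors"]]
        return cls(**kwargs)


@dataclass(frozen=True)
class TurnRecord:
    """Everything observed and decided during one interaction turn."""

    turn_index: int
    item_id: int
    style_index: int
    style_name: str
    thetas: Optional[list[float]]
    reward: Optional[float]
    frame_count: int
    delta: Optional[float]
    outcome: str  # "success" | "failure" | "none"
    alpha_after: list[float]
    beta_after: list[float]
    response: int
    frames: Optional[list[str]] = None


@dataclass
class SessionLog:
    """Complete record of one session: config echo, turns, final arms."""

    user_id: str
    config: SessionConfig
    records: list[TurnRecord]
    final_alpha: dict[str, float]
    final_beta: dict[str, float]
    prior_alpha: dict[str, float]
    prior_beta: dict[str, float]
    r0: float = 0.0  # initial reward baseline, logged only

    @property
    def style_names(self) -> list[str]:
        return list(self.final_alpha)

    def updates_applied(self) -> int:
        return sum(1 for r in self.records if r.outcome != "none")


def run_session(
    config: SessionConfig,
    user,
    script: Optional[Sequence[ScriptItem]] = None,
    policy: Optional[PolicyState] = None,
) -> SessionLog:
    """Execute one full adaptive session and return its log.

    The master seed is split into independent sub-streams for the policy,
    the user's frame emission, and the (logged-only) numerical item
    responses, so logs are reproducible regardless of module call order.
    The user's numerical rating is recorded but never reaches the policy.
    """
    if script is None:
        script = make_default_script(max(config.n_turns, 32))
    if config.n_turns > len(script):
        raise ValueError(
            f"n_turns={config.n_turns} exceeds script length {len(script)}"
        )
    policy_ss, user_ss, response_ss = np.random.SeedSequence(config.seed).spawn(3)
    if policy is None:
        policy = init_policy(
            n_styles=len(config.style_names),
            priors=config.priors,
            names=config.style_names,
            rng=np.random.default_rng(policy_ss),
            seed=config.seed,
        )
    user_rng = np.random.default_rng(user_ss)
    response_rng = np.random.default_rng(response_ss)
    valence_map = config.valence_map

    prior_alpha = {s.name: a.prior_alpha for s, a in zip(policy.styles, policy.arms)}
    prior_beta = {s.name: a.prior_beta for s, a in zip(policy.styles, policy.arms)}

    records: list[TurnRecord] = []
    previous: Optional[TurnReward] = None
    for t in range(1, config.n_turns + 1):
        item = script[t - 1]
        if config.policy == "thompson":
            chosen, thetas_arr = sample_and_select(policy)
            thetas: Optional[list[float]] = [float(x) for x in thetas_arr]
        else:
            chosen = baseline_select(
                policy, config.policy, epsilon=config.epsilon, c=config.ucb_c
            )
            thetas = None

        frames = user.frames_for_turn(t, chosen, config.frames_per_turn, user_rng)
        if len(frames) == 0 and not config.lenient_empty_turns:
            raise EmptyTurnError(
                f"no emotion frames observed at turn {t} (strict mode)"
            )

        reward: Optional[float] = None
        delta: Optional[float] = None
        outcome = "none"
        frame_count = len(frames)
        if frame_count > 0:
            turn_reward = compute_turn_reward(frames, valence_map, turn_index=t)
            reward = turn_reward.reward
            if previous is not None:
                if previous.turn_index == t - 1:
                    delta = compute_delta(turn_reward, previous)
                else:  # a lenient empty turn intervened
                    delta = turn_reward.reward - previous.reward
                update_from_delta(policy, chosen, delta)
                outcome = "success" if delta >= 0 else "failure"
            previous = turn_reward
            policy.last_reward = reward

        records.append(
            TurnRecord(
                turn_index=t,
                item_id=item.item_id,
                style_index=chosen.index,
                style_name=chosen.name,
                thetas=thetas,
                reward=reward,
                frame_count=frame_count,
                delta=delta,
                outcome=outcome,
                alpha_after=[a.alpha for a in policy.arms],
                beta_after=[a.beta for a in policy.arms],
                response=int(response_rng.integers(1, 6)),
                frames=[f.label.value for f in frames] if config.log_frames else None,
            )
        )

    user_id = getattr(user, "user_id", "anonymous")
    return SessionLog(
        user_id=user_id,
        config=config,
        records=records,
        final_alpha={s.name: a.alpha for s, a in zip(policy.styles, policy.arms)},
        final_beta={s.name: a.beta for s, a in zip(policy.styles, policy.arms)},
        prior_alpha=prior_alpha,
        prior_beta=prior_beta,
    )


def run_cohort(
    cohort: Sequence[UserProfile],
    config: SessionConfig,
    script: Optional[Sequence[ScriptItem]] = None,
) -> list[SessionLog]:
    """Run one independent session per profile with derived sub-seeds."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    children = np.random.SeedSequence(config.seed).spawn(len(cohort))
    logs = []
    for profile, child in zip(cohort, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        sub_config = dataclasses.replace(config, seed=sub_seed)
        logs.append(run_session(sub_config, SimulatedUser(profile), script=script))
    return logs


def classify_dominant_style(
    final_alpha: Union[Mapping[str, float], SessionLog],
    margin: float = 2.0,
) -> str:
    """Name the style with the higher final alpha, if it leads by ``margin``.

    An exact tie is never a preference; otherwise the leader must be ahead
    by at least ``margin`` successes, else ``"no clear preference"``.
    """
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    if isinstance(final_alpha, SessionLog):
        final_alpha = final_alpha.final_alpha
    ordered = sorted(final_alpha.items(), key=lambda kv: -kv[1])
    (best, a1), (_, a2) = ordered[0], ordered[1]
    if a1 == a2 or a1 - a2 < margin:
        return NO_CLEAR_PREFERENCE
    return best


# ---------------------------------------------------------------------------
# JSONL serialisation: one TurnRecord per line, then a footer object with
# the config echo and final state.
# ---------------------------------------------------------------------------


def write_session_log(log: SessionLog, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in log.records:
            fh.write(json.dumps(dataclasses.asdict(rec)) + "\n")
        footer = {
            "final": {
                "user_id": log.user_id,
                "alpha": log.final_alpha,
                "beta": log.final_beta,
                "prior_alpha": log.prior_alpha,
                "prior_beta": log.prior_beta,
                "r0": log.r0,
            },
            "config": _config_to_jsonable(log.config),
        }
        fh.write(json.dumps(footer) + "\n")


def read_session_log(path: Union[str, Path]) -> SessionLog:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"empty session log {path}")
    *record_lines, footer_line = lines
    footer = json.loads(footer_line)
    if "final" not in footer:
        raise ValueError(f"session log {path} is missing its footer")
    records = [TurnRecord(**json.loads(line)) for line in record_lines]
    cfg = footer["config"]
    if cfg.get("priors") is not None:
        cfg["priors"] = [tuple(p) for p in cfg["priors"]]
    cfg["style_names"] = tuple(cfg["style_names"])
    return SessionLog(
        user_id=footer["final"]["user_id"],
        config=SessionConfig(**cfg),
        records=records,
        final_alpha=footer["final"]["alpha"],
        final_beta=footer["final"]["beta"],
        prior_alpha=footer["final"]["prior_alpha"],
        prior_beta=footer["final"]["prior_beta"],
        r0=footer["final"].get("r0", 0.0),
    )


def _config_to_jsonable(config: SessionConfig) -> dict:
    payload = dataclasses.asdict(config)
    payload["style_names"] = list(config.style_names)
    if config.priors is not None:
        payload["priors"] = [list(p) for p in config.priors]
    if config.valence_scores is not None:
        payload["valence_scores"] = dict(config.valence_scores)
    return payload


def cohort_summary(
    logs: Sequence[SessionLog], margin: float = 2.0
) -> pd.DataFrame:
    """Per-user final arm counts and dominant-style call, one row per user."""
    rows = []
    for log in logs:
        row: dict = {"user_id": log.user_id}
        for name in log.style_names:
            row[f"alpha_{name}"] = log.final_alpha[name]
            row[f"beta_{name}"] = log.final_beta[name]
        row["dominant"] = classify_dominant_style(log, margin=margin)
        rows.append(row)
    return pd.DataFrame(rows)
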