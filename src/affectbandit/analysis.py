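"""Session-log analysis: learning trajectories, correlations, regret.

The evaluation questions mirror those asked of the live system: how the
per-style success counts (alpha values) evolve over turns, whether the final
counts rank-correlate with a personality trait across users, and how much
expected success a selection policy forfeits relative to always playing the
best style (cumulative regret).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .session import SessionLog


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with a two-sided p-value."""

    rho: float
    p_value: float
    n: int


def alpha_trajectories(log: SessionLog) -> pd.DataFrame:
    """Per-turn post-update Beta parameters, one row per turn.

    Columns: ``turn`` plus ``alpha_<style>`` and ``beta_<style>`` per style.
    """
    names = log.style_names
    rows = []
    for rec in log.records:
        row: dict = {"turn": rec.turn_index}
        for i, name in enumerate(names):
            row[f"alpha_{name}"] = rec.alpha_after[i]
            row[f"beta_{name}"] = rec.beta_after[i]
        rows.append(row)
    return pd.DataFrame(rows)


def spearman_correlation(
    x: Sequence[float], y: Sequence[float]
) -> CorrelationResult:
    """Spearman's rho on average ranks, with a two-sided p-value.

    For n <= 10 the p-value is exact, from full enumeration of the n!
    pairings; for larger n the usual t approximation with n - 2 degrees of
    freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"x and y must be equal-length 1-d sequences, got {x.shape} and {y.shape}"
        )
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    if denom == 0.0:
        raise ValueError("constant input: Spearman's rho is undefined")
    rho = float(rxc @ ryc) / denom

    if n <= 10:
        p = _exact_permutation_pvalue(rxc, ryc, denom, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p_value=min(p, 1.0), n=n)


def _exact_permutation_pvalue(
    rxc: np.ndarray, ryc: np.ndarray, denom: float, rho_obs: float
) -> float:
    """P(|rho_perm| >= |rho_obs|) over all pairings of the rank vectors."""
    n = len(rxc)
    threshold = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    chunk: list[tuple] = []
    chunk_size = 40320
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == chunk_size:
            count += _count_extreme(chunk, rxc, ryc, denom, threshold)
            total += len(chunk)
            chunk = []
    if chunk:
        count += _count_extreme(chunk, rxc, ryc, denom, threshold)
        total += len(chunk)
    return count / total


def _count_extreme(chunk, rxc, ryc, denom, threshold) -> int:
    perms = np.array(chunk)
    rhos = (ryc[perms] @ rxc) / denom
    return int(np.sum(np.abs(rhos) >= threshold))


def trait_style_correlation(
    logs: Sequence[SessionLog],
    traits: Mapping[str, float],
    style: str,
) -> CorrelationResult:
    """Rank correlation between user trait and final alpha of one style."""
    missing = [log.user_id for log in logs if log.user_id not in traits]
    if missing:
        raise KeyError(f"no trait value for users: {missing}")
    trait_values = [traits[log.user_id] for log in logs]
    final_alphas = [log.final_alpha[style] for log in logs]
    return spearman_correlation(trait_values, final_alphas)


def cumulative_regret(
    log: SessionLog, success_probs: Mapping[str, float]
) -> float:
    """Total expected-success shortfall versus always playing the best style.

    ``success_probs`` is the simulator's ground truth, keyed by style name.
    """
    best = max(success_probs.values())
    regret = 0.0
    for rec in log.records:
        if rec.style_name not in success_probs:
            raise KeyError(
                f"style {rec.style_name!r} in log has no configured "
                "success probability"
            )
        regret += best - success_probs[rec.style_name]
    return regret


def regret_curve(
    log: SessionLog, success_probs: Mapping[str, float]
) -> np.ndarray:
    """Running cumulative regret after each turn (non-decreasing)."""
    best = max(success_probs.values())
    per_turn = np.array(
        [best - success_probs[rec.style_name] for rec in log.records]
    )
    return np.cumsum(per_turn)


def correlations_table(
    logs: Sequence[SessionLog], traits: Mapping[str, float]
) -> pd.DataFrame:
    """Trait-vs-final-alpha Spearman correlations, one row per style."""
    rows = []
    for style in logs[0].style_names:
        res = trait_style_correlation(logs, traits, style)
        rows.append(
            {"style": style, "rho": res.rho, "p_value": res.p_value, "n": res.n}
        )
    return pd.DataFrame(rows)
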