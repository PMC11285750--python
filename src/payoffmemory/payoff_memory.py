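"""Recalled payoffs and imitation probabilities under limited payoff memory.

In the pairwise-comparison (Fermi) imitation process, a learner compares its
own payoff ``pi_L`` with a role model's payoff ``pi_RM`` and copies the role
model's strategy with probability ``1 / (1 + exp(-beta * (pi_RM - pi_L)))``.
The classical model feeds *expected* payoffs into this comparison (perfect
payoff memory).  Here the comparison payoffs may instead be the payoffs a
player actually realized recently:

``perfect``
    deterministic expected payoff, averaged over all ``N - 1`` co-players;
``last_rounds(k, m)``
    the mean of the realized payoffs from the last ``k`` rounds of games
    against ``m`` recent co-players (each co-player drawn independently from
    the rest of the population);
``game_average``
    the expected (per-round average) payoff of a single repeated game
    against one random co-player.

Because recalled payoffs are random, the effective probability that a
learner copies a role model is the expectation of the Fermi function over
the joint draw of the two recalled payoffs; learner and role-model draws
are treated as independent (a well-mixed, large-``N`` approximation that
ignores the O(1/N) chance that the two recently played each other).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import expit

from .games import GameSpec
from .repeated_game import (
    PayoffDistribution,
    Strategy,
    expected_payoff,
    game_average_payoff_distribution,
    last_k_payoff_distribution,
)

__all__ = [
    "MemoryModel",
    "PERFECT",
    "LAST_ROUND",
    "GAME_AVERAGE",
    "PopulationContext",
    "fermi_probability",
    "recalled_payoff_distribution",
    "effective_imitation_probability",
    "strong_selection_comparison",
]

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class MemoryModel:
    """How a player forms the payoff it brings to a social comparison.

    ``variant`` is one of ``"perfect"``, ``"last_rounds"`` or
    ``"game_average"``.  For ``last_rounds``, ``k`` is the number of recalled
    rounds per co-player and ``m`` the number of recalled co-players; the
    single-round baseline of the limited-memory model is ``k = m = 1``.
    """

    variant: Literal["perfect", "last_rounds", "game_average"]
    k: int = 1
    m: int = 1

    def __post_init__(self) -> None:
        if self.variant not in ("perfect", "last_rounds", "game_average"):
            raise ValueError(f"unknown memory variant {self.variant!r}")
        if self.variant == "last_rounds" and (self.k < 1 or self.m < 1):
            raise ValueError("last_rounds memory needs k >= 1 and m >= 1")

    def label(self) -> str:
        if self.variant == "last_rounds":
            return f"last_rounds(k={self.k}, m={self.m})"
        return self.variant


PERFECT = MemoryModel("perfect")
LAST_ROUND = MemoryModel("last_rounds", k=1, m=1)
GAME_AVERAGE = MemoryModel("game_average")


@dataclass(frozen=True)
class PopulationContext:
    """A two-strategy population state: ``j`` mutants among ``N`` players.

    ``N = math.inf`` encodes the large-population single-mutant limit used in
    the stability analysis: there, every player's co-players are residents
    with probability one.
    """

    resident: Strategy
    mutant: Strategy
    j: int
    N: float

    def __post_init__(self) -> None:
        if not (self.N == math.inf or (isinstance(self.N, (int, float)) and self.N >= 2)):
            raise ValueError("N must be >= 2 (or math.inf)")
        if math.isfinite(self.N) and not (0 <= self.j <= self.N):
            raise ValueError(f"j={self.j} outside [0, N={self.N}]")

    def partner_is_mutant_prob(self, role: str) -> float:
        """Probability that a random co-player of a ``role`` player is a
        mutant; a player is never its own co-player."""
        if self.N == math.inf:
            return 0.0
        if role == "mutant_member":
            return (self.j - 1) / (self.N - 1)
        if role == "resident_member":
            return self.j / (self.N - 1)
        raise ValueError(f"unknown role {role!r}")


def fermi_probability(pi_l: float, pi_rm: float, beta: float) -> float:
    """Probability that the learner adopts the role model's strategy,
    ``1 / (1 + exp(-beta * (pi_RM - pi_L)))``, computed overflow-safely."""
    if beta < 0:
        raise ValueError("selection strength beta must be >= 0")
    return float(expit(beta * (pi_rm - pi_l)))


def _check_role(role: str, ctx: PopulationContext) -> None:
    if role == "mutant_member":
        if ctx.j < 1:
            raise ValueError("a mutant member requires j >= 1")
    elif role == "resident_member":
        if math.isfinite(ctx.N) and ctx.j > ctx.N - 1:
            raise ValueError("a resident member requires j <= N - 1")
    else:
        raise ValueError(f"unknown role {role!r}")


def _own_and_partner(role: str, ctx: PopulationContext) -> Strategy:
    return ctx.mutant if role == "mutant_member" else ctx.resident


def recalled_payoff_distribution(
    role: Literal["resident_member", "mutant_member"],
    ctx: PopulationContext,
    memory: MemoryModel,
    delta: float,
    game: GameSpec,
) -> PayoffDistribution:
    """Distribution of the payoff a ``role`` player brings to a comparison.

    For the stochastic memory models this is a mixture over the co-player's
    type (mutant with probability ``(j-1)/(N-1)`` for a mutant focal player,
    ``j/(N-1)`` for a resident one) of per-co-player recall distributions;
    for ``m >= 2`` co-players it is the distribution of the mean of ``m``
    independent such draws.  Perfect memory gives a point mass at the
    type-weighted average expected payoff.
    """
    _check_role(role, ctx)
    own = _own_and_partner(role, ctx)
    alpha = ctx.partner_is_mutant_prob(role)

    if memory.variant == "perfect":
        pi_m = expected_payoff(own, ctx.mutant, delta, game)
        pi_r = expected_payoff(own, ctx.resident, delta, game)
        return PayoffDistribution.point_mass(alpha * pi_m + (1 - alpha) * pi_r)

    if memory.variant == "game_average":
        d_m = game_average_payoff_distribution(own, ctx.mutant, delta, game)
        d_r = game_average_payoff_distribution(own, ctx.resident, delta, game)
        return _mix(alpha, d_m, d_r)

    d_m = last_k_payoff_distribution(own, ctx.mutant, delta, game, memory.k)
    d_r = last_k_payoff_distribution(own, ctx.resident, delta, game, memory.k)
    one_draw = _mix(alpha, d_m, d_r)
    if memory.m == 1:
        return one_draw
    return PayoffDistribution.mean_of_iid(one_draw, memory.m)


def _mix(
    alpha: float, d_mut: PayoffDistribution, d_res: PayoffDistribution
) -> PayoffDistribution:
    if alpha <= 0.0:
        return d_res
    if alpha >= 1.0:
        return d_mut
    return PayoffDistribution.mixture([(alpha, d_mut), (1 - alpha, d_res)])


def effective_imitation_probability(
    learner_role: str,
    rolemodel_role: str,
    ctx: PopulationContext,
    memory: MemoryModel,
    beta: float,
    delta: float,
    game: GameSpec,
) -> float:
    """Expected Fermi acceptance probability over independent draws of the
    learner's and role model's recalled payoffs (exact finite sum over the
    product support)."""
    if beta < 0:
        raise ValueError("selection strength beta must be >= 0")
    d_l = recalled_payoff_distribution(learner_role, ctx, memory, delta, game)
    d_rm = recalled_payoff_distribution(rolemodel_role, ctx, memory, delta, game)
    diff = d_rm.support[None, :] - d_l.support[:, None]
    phi = expit(beta * diff)
    return float(d_l.probs @ phi @ d_rm.probs)


def strong_selection_comparison(
    ctx: PopulationContext,
    memory: MemoryModel,
    delta: float,
    game: GameSpec,
) -> tuple[float, float, float]:
    """Exact probabilities that a mutant's recalled payoff exceeds / falls
    below / ties a resident's, under independent draws.

    In the strong-selection limit of the Fermi rule the learner copies the
    role model whenever the role model's payoff is strictly higher, and with
    probability one half on a tie, so these three numbers determine the
    imitation flow between the two types.  Returns ``(P_up, P_down, P_tie)``
    with ``P_up = P(pi_mutant > pi_resident)``.
    """
    d_m = recalled_payoff_distribution("mutant_member", ctx, memory, delta, game)
    d_r = recalled_payoff_distribution("resident_member", ctx, memory, delta, game)
    diff = d_m.support[:, None] - d_r.support[None, :]
    joint = d_m.probs[:, None] * d_r.probs[None, :]
    p_up = float(joint[diff > _TIE_TOL].sum())
    p_down = float(joint[diff < -_TIE_TOL].sum())
    p_tie = 1.0 - p_up - p_down
    return p_up, p_down, max(p_tie, 0.0)
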