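"""Stochastic stability of cooperative residents against always-defect.

A fully cooperative resident population plays Generous Tit-for-Tat,
``GTFT = (1, 1, q)``.  Cooperation is called *stochastically stable* if a
single always-defect (ALLD) mutant, in a large population under strong
selection, is more likely to imitate the residents than the residents are to
imitate it.  With perfect payoff memory this reduces to comparing expected
payoffs; with stochastic payoff memory it compares the probabilities that
one player's recalled payoff exceeds the other's (ties push equally both
ways and therefore cancel).

The maximum generosity ``q_max`` compatible with stability has closed forms
in the cases worked out analytically:

=====================  ===========  =======================
memory                 game         threshold on q
=====================  ===========  =======================
perfect                donation     ``1 - c / (delta * b)``
perfect                snowdrift    ``1 - c / (2 * delta * b)``
last round, 1 partner  either       ``1 - 1 / (2 * delta)``
two recalled payoffs   donation     ``sqrt(2) / 2`` (b > 2c, delta -> 1)
game average           donation     ``1 - c / b`` (delta -> 1)
=====================  ===========  =======================

"two recalled payoffs" covers both the last two rounds of one interaction
(k=2, m=1) and the last rounds of two interactions (k=1, m=2).  For every
other memory/game combination :func:`threshold_bisection` finds the
threshold numerically from the same strong-selection comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .games import GameSpec
from .payoff_memory import (
    MemoryModel,
    PopulationContext,
    strong_selection_comparison,
)
from .repeated_game import ALLD, expected_payoff, gtft

__all__ = [
    "StabilityResult",
    "is_stochastically_stable",
    "closed_form_threshold",
    "threshold_bisection",
    "feasibility_delta",
]

#: continuation probabilities at least this close to 1 count as the
#: "delta -> 1" regime in which the two-recall and game-average closed
#: forms were derived
_DELTA_NEAR_ONE = 1.0 - 1e-3


@dataclass(frozen=True)
class StabilityResult:
    """Maximum-generosity threshold for one memory model and game.

    ``feasible`` is False when no generosity level ``q >= 0`` is stable (the
    resident loses to ALLD even at q = 0, i.e. as Tit-for-Tat)."""

    q_max: Optional[float]
    feasible: bool
    method: str
    memory: MemoryModel
    game: str
    delta: float


def is_stochastically_stable(
    q: float,
    memory: MemoryModel,
    delta: float,
    game: GameSpec,
) -> bool:
    """Is a GTFT(q) resident stable against a single ALLD mutant?

    Large population, strong selection.  Perfect memory compares expected
    payoffs; stochastic memories compare the realized-payoff distributions
    via :func:`strong_selection_comparison`.  Equality at the boundary
    counts as unstable (the stability conditions are strict).
    """
    resident = gtft(q)
    ctx = PopulationContext(resident=resident, mutant=ALLD, j=1, N=math.inf)
    if memory.variant == "perfect":
        pi_res = expected_payoff(resident, resident, delta, game)
        pi_mut = expected_payoff(ALLD, resident, delta, game)
        return pi_res > pi_mut + 1e-15
    p_up, p_down, _ = strong_selection_comparison(ctx, memory, delta, game)
    return p_down > p_up + 1e-15


def closed_form_threshold(
    memory: MemoryModel, game: GameSpec, b: float, c: float, delta: float
) -> StabilityResult:
    """Evaluate the analytic generosity threshold where one is known.

    Raises ``ValueError`` for memory/game combinations without a derived
    closed form (use :func:`threshold_bisection` there).  The two-recall and
    game-average formulas hold in the delta -> 1 limit and are only reported
    for delta >= 0.999; the two-recall donation formula additionally
    requires b > 2c.
    """
    variant = memory.variant
    q_max: Optional[float] = None
    if variant == "perfect":
        if game.name == "donation":
            q_max = 1.0 - c / (delta * b)
        elif game.name == "snowdrift":
            q_max = 1.0 - c / (2.0 * delta * b)
    elif variant == "last_rounds" and memory.k == 1 and memory.m == 1:
        if game.name in ("donation", "snowdrift"):
            q_max = 1.0 - 1.0 / (2.0 * delta)
    elif variant == "last_rounds" and {memory.k, memory.m} == {1, 2}:
        if game.name == "donation" and b > 2 * c and delta >= _DELTA_NEAR_ONE:
            q_max = math.sqrt(2.0) / 2.0
    elif variant == "game_average":
        if game.name == "donation" and delta >= _DELTA_NEAR_ONE:
            q_max = 1.0 - c / b
    if q_max is None:
        raise ValueError(
            f"no closed-form threshold for memory {memory.label()} on the "
            f"{game.name} game at delta={delta}; use threshold_bisection"
        )
    return StabilityResult(
        q_max=q_max,
        feasible=q_max >= 0.0,
        method="closed_form",
        memory=memory,
        game=game.name,
        delta=delta,
    )


def threshold_bisection(
    memory: MemoryModel,
    delta: float,
    game: GameSpec,
    tol: float = 1e-9,
) -> StabilityResult:
    """Numeric generosity threshold by bisection on the stability indicator.

    Checks monotonicity at the bracket ends first: stability must hold at
    q = 0 (else the result is infeasible) and fail at q = 1.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not is_stochastically_stable(0.0, memory, delta, game):
        return StabilityResult(
            q_max=None,
            feasible=False,
            method="bisection",
            memory=memory,
            game=game.name,
            delta=delta,
        )
    if is_stochastically_stable(1.0, memory, delta, game):
        # stable over the whole range; full generosity is sustainable
        return StabilityResult(
            q_max=1.0,
            feasible=True,
            method="bisection",
            memory=memory,
            game=game.name,
            delta=delta,
        )
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if is_stochastically_stable(mid, memory, delta, game):
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return StabilityResult(
        q_max=0.5 * (lo + hi),
        feasible=True,
        method="bisection",
        memory=memory,
        game=game.name,
        delta=delta,
    )


def feasibility_delta(memory: MemoryModel, game: GameSpec, b: float, c: float) -> float:
    """Smallest continuation probability at which any nonnegative generosity
    is stable (``q_max >= 0``)."""
    if memory.variant == "perfect":
        if game.name == "donation":
            return c / b
        if game.name == "snowdrift":
            return c / (2.0 * b)
    if memory.variant == "last_rounds" and memory.k == 1 and memory.m == 1:
        if game.name in ("donation", "snowdrift"):
            return 0.5
    raise ValueError(
        f"no feasibility bound derived for memory {memory.label()} on the "
        f"{game.name} game"
    )
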