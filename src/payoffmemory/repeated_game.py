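"""Exact algebra of the discounted repeated game between two strategies.

The repeated game has a geometric length: after every round the interaction
continues with probability ``delta``, so the final round index ``T``
satisfies ``P(T = t) = (1 - delta) * delta**t``.  For a pair of reactive (or
memory-one) strategies, the joint action in consecutive rounds forms a
Markov chain over the four states ``(CC, CD, DC, DD)``; everything in this
module is derived from that chain.

The central object for the limited-payoff-memory model is the distribution
of the payoff a player *realizes* in the last round (or the mean over the
last ``k`` rounds) of a game — as opposed to the expected payoff used by the
classical model.  A useful identity connects the two: the mean of the
last-round payoff distribution equals the normalized discounted expected
payoff ``(1 - delta) * sum_t delta**t * u_t``, because the state of the
final round is distributed exactly as the discount-weighted mixture of
per-round states.

A Monte-Carlo play oracle (:func:`simulate_repeated_game`) is provided for
testing the closed forms by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .games import GameSpec

__all__ = [
    "ReactiveStrategy",
    "MemoryOneStrategy",
    "Strategy",
    "PayoffDistribution",
    "ALLD",
    "TFT",
    "gtft",
    "transition_matrix",
    "opening_distribution",
    "discounted_state_distribution",
    "expected_payoff",
    "cooperation_rate",
    "last_round_payoff_distribution",
    "last_k_payoff_distribution",
    "game_average_payoff_distribution",
    "simulate_repeated_game",
]

_MERGE_TOL = 1e-9  # payoff values closer than this are merged in distributions


@dataclass(frozen=True)
class ReactiveStrategy:
    """Reactive repeated-game strategy ``(y, p, q)``.

    ``y`` is the probability of cooperating in the opening round; ``p`` and
    ``q`` are the probabilities of cooperating after the *partner* cooperated
    or defected in the previous round.  The strategy ignores the player's own
    previous action.
    """

    y: float
    p: float
    q: float

    def __post_init__(self) -> None:
        for name in ("y", "p", "q"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_memory_one(self) -> "MemoryOneStrategy":
        """Embed as a memory-one strategy (own previous action is ignored)."""
        return MemoryOneStrategy(self.y, self.p, self.q, self.p, self.q)

    def coop_probs(self) -> np.ndarray:
        """Cooperation probability in the next round per joint state
        ``(CC, CD, DC, DD)``, states read as (own, partner)."""
        return np.array([self.p, self.q, self.p, self.q], dtype=float)


@dataclass(frozen=True)
class MemoryOneStrategy:
    """Memory-one strategy ``(y; p_CC, p_CD, p_DC, p_DD)``.

    Conditional cooperation probabilities are indexed by the previous joint
    action (own action first).  A :class:`ReactiveStrategy` embeds via
    ``p_CC = p_DC = p`` and ``p_CD = p_DD = q``.
    """

    y: float
    p_cc: float
    p_cd: float
    p_dc: float
    p_dd: float

    def __post_init__(self) -> None:
        for name in ("y", "p_cc", "p_cd", "p_dc", "p_dd"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_memory_one(self) -> "MemoryOneStrategy":
        return self

    def coop_probs(self) -> np.ndarray:
        return np.array([self.p_cc, self.p_cd, self.p_dc, self.p_dd], dtype=float)


Strategy = Union[ReactiveStrategy, MemoryOneStrategy]

#: Always defect.
ALLD = ReactiveStrategy(0.0, 0.0, 0.0)
#: Tit-for-Tat: cooperate first, then mirror the partner's last action.
TFT = ReactiveStrategy(1.0, 1.0, 0.0)


def gtft(q: float) -> ReactiveStrategy:
    """Generous Tit-for-Tat ``(1, 1, q)``: always reciprocate cooperation and
    forgive a defection with probability ``q``."""
    return ReactiveStrategy(1.0, 1.0, q)


class PayoffDistribution:
    """Finite-support distribution of a recalled payoff.

    Support values are kept sorted and distinct (merged within 1e-9);
    probabilities are nonnegative and sum to one.
    """

    __slots__ = ("support", "probs")

    def __init__(self, support: Sequence[float], probs: Sequence[float]):
        support = np.asarray(support, dtype=float)
        probs = np.asarray(probs, dtype=float)
        if support.shape != probs.shape or support.ndim != 1:
            raise ValueError("support and probs must be 1-D arrays of equal length")
        if np.any(probs < -1e-12):
            raise ValueError("negative probability")
        total = probs.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")
        support, probs = _merge_support(support, probs)
        self.support = support
        self.probs = probs / probs.sum()

    def mean(self) -> float:
        return float(self.support @ self.probs)

    def __len__(self) -> int:
        return len(self.support)

    def __repr__(self) -> str:  # pragma: no cover
        pairs = ", ".join(
            f"{v:g}: {p:.6g}" for v, p in zip(self.support, self.probs)
        )
        return f"PayoffDistribution({{{pairs}}})"

    @staticmethod
    def point_mass(value: float) -> "PayoffDistribution":
        return PayoffDistribution([value], [1.0])

    @staticmethod
    def mixture(
        components: Sequence[tuple[float, "PayoffDistribution"]],
    ) -> "PayoffDistribution":
        """Mixture ``sum_i w_i * D_i`` with nonnegative weights summing to 1."""
        support = np.concatenate([d.support for _, d in components])
        probs = np.concatenate([w * d.probs for w, d in components])
        return PayoffDistribution(*_merge_support(support, probs))

    @staticmethod
    def mean_of_iid(dist: "PayoffDistribution", m: int) -> "PayoffDistribution":
        """Distribution of the arithmetic mean of ``m`` independent draws."""
        if m < 1:
            raise ValueError("m must be >= 1")
        sup = np.zeros(1)
        pr = np.ones(1)
        for _ in range(m):
            sup = (sup[:, None] + dist.support[None, :]).ravel()
            pr = (pr[:, None] * dist.probs[None, :]).ravel()
            sup, pr = _merge_support(sup, pr)
        return PayoffDistribution(sup / m, pr)


def _merge_support(
    support: np.ndarray, probs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sort support, merge values within the merge tolerance, drop zero mass."""
    order = np.argsort(support)
    support = support[order]
    probs = probs[order]
    if len(support) > 1:
        new_group = np.diff(support) > _MERGE_TOL
        group = np.concatenate([[0], np.cumsum(new_group)])
        n_groups = group[-1] + 1
        merged_p = np.bincount(group, weights=probs, minlength=n_groups)
        # representative value: the group's first support value (keeps exact
        # payoff values exact; group spread is below the merge tolerance)
        first_idx = np.searchsorted(group, np.arange(n_groups))
        support, probs = support[first_idx], merged_p
    keep = probs > 1e-15
    if not keep.any():
        keep = np.ones_like(probs, dtype=bool)
    return support[keep], probs[keep]


def _check_delta(delta: float) -> None:
    if not (0.0 <= delta < 1.0):
        raise ValueError(
            f"delta={delta} must lie in [0, 1); for the delta -> 1 limit use "
            "a proxy such as 1 - 1e-6"
        )


def transition_matrix(s_focal: Strategy, s_partner: Strategy) -> np.ndarray:
    """Row-stochastic 4x4 transition matrix of the joint-action chain.

    States are ordered ``(CC, CD, DC, DD)`` from the focal player's
    perspective.  Each entry is the product of the two players' conditional
    cooperation/defection probabilities given the previous joint action.
    """
    x = s_focal.as_memory_one().coop_probs()  # focal coop prob per state
    # partner sees the state with roles swapped: (partner's own, focal)
    z_all = s_partner.as_memory_one().coop_probs()
    z = z_all[[0, 2, 1, 3]]
    m = np.empty((4, 4), dtype=float)
    m[:, 0] = x * z
    m[:, 1] = x * (1.0 - z)
    m[:, 2] = (1.0 - x) * z
    m[:, 3] = (1.0 - x) * (1.0 - z)
    return m


def opening_distribution(s_focal: Strategy, s_partner: Strategy) -> np.ndarray:
    """Distribution of the round-0 joint action (outer product of the y's)."""
    yf = s_focal.y
    yp = s_partner.y
    return np.array(
        [yf * yp, yf * (1 - yp), (1 - yf) * yp, (1 - yf) * (1 - yp)], dtype=float
    )


def discounted_state_distribution(
    s_focal: Strategy, s_partner: Strategy, delta: float
) -> np.ndarray:
    """Distribution of the joint action in the *final* round of the game.

    With geometric game length, the final-round state distribution is the
    discount-weighted mixture of per-round distributions,

    ``w = (1 - delta) * v0 @ inv(I - delta * M)``,

    where ``v0`` is the opening distribution and ``M`` the transition
    matrix.  Valid for ``0 <= delta < 1``; at ``delta = 0`` it reduces to
    ``v0``.
    """
    _check_delta(delta)
    v0 = opening_distribution(s_focal, s_partner)
    m = transition_matrix(s_focal, s_partner)
    a = np.eye(4) - delta * m
    w = (1.0 - delta) * np.linalg.solve(a.T, v0)
    # guard against tiny negative round-off
    w = np.clip(w, 0.0, None)
    return w / w.sum()


def expected_payoff(
    s_focal: Strategy, s_partner: Strategy, delta: float, game: GameSpec
) -> float:
    """Normalized discounted expected payoff ``(1-delta) * sum_t delta^t u_t``.

    Computed as the dot product of the discounted state distribution with
    the focal payoff vector.
    """
    w = discounted_state_distribution(s_focal, s_partner, delta)
    return float(w @ game.focal_payoffs)


def cooperation_rate(s_focal: Strategy, s_partner: Strategy, delta: float) -> float:
    """Discount-weighted probability that the focal player cooperates,
    ``w(CC) + w(CD)``."""
    w = discounted_state_distribution(s_focal, s_partner, delta)
    return float(w[0] + w[1])


def last_round_payoff_distribution(
    s_focal: Strategy, s_partner: Strategy, delta: float, game: GameSpec
) -> PayoffDistribution:
    """Distribution of the focal payoff realized in the final round.

    This is the payoff a player with single-round payoff memory brings to a
    social comparison.  Its mean equals :func:`expected_payoff`.
    """
    w = discounted_state_distribution(s_focal, s_partner, delta)
    return PayoffDistribution(*_merge_support(game.focal_payoffs.copy(), w.copy()))


def last_k_payoff_distribution(
    s_focal: Strategy,
    s_partner: Strategy,
    delta: float,
    game: GameSpec,
    k: int,
) -> PayoffDistribution:
    """Distribution of the mean focal payoff over the last ``min(k, length)``
    rounds of the game.

    Exact for any ``k``: games of length ``>= k`` contribute paths of ``k``
    joint states started from the discounted state distribution of the
    ``(k-1)``-th-from-last round, and the finitely many shorter games
    (probability mass ``1 - delta**(k-1)``) are enumerated directly, with the
    average taken over the rounds that exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    _check_delta(delta)
    if k == 1:
        return last_round_payoff_distribution(s_focal, s_partner, delta, game)

    pay = game.focal_payoffs
    m = transition_matrix(s_focal, s_partner)
    v0 = opening_distribution(s_focal, s_partner)

    support: list[np.ndarray] = []
    probs: list[np.ndarray] = []

    def enumerate_paths(start: np.ndarray, steps: int) -> tuple[np.ndarray, np.ndarray]:
        """Sum of payoffs along all state paths of ``steps + 1`` states.

        Returns (payoff sums, path probabilities) over the 4**(steps+1)
        paths, starting from distribution ``start``.
        """
        sums = pay.copy()
        pr = start.copy()
        states = np.arange(4)
        for _ in range(steps):
            sums = (sums[:, None] + pay[None, :]).ravel()
            pr = (pr[:, None] * m[states][:, :]).ravel()
            states = np.tile(np.arange(4), len(states))
        return sums, pr

    # games with fewer than k rounds: final index t in {0, ..., k-2}
    for t in range(k - 1):
        sums, pr = enumerate_paths(v0, t)
        support.append(sums / (t + 1))
        probs.append((1.0 - delta) * delta**t * pr)

    # games with at least k rounds: the state k-1 rounds before the end is
    # distributed as the discounted state distribution, with total mass
    # delta**(k-1)
    w = discounted_state_distribution(s_focal, s_partner, delta)
    sums, pr = enumerate_paths(w, k - 1)
    support.append(sums / k)
    probs.append(delta ** (k - 1) * pr)

    sup = np.concatenate(support)
    pr = np.concatenate(probs)
    return PayoffDistribution(*_merge_support(sup, pr))


def game_average_payoff_distribution(
    s_focal: Strategy, s_partner: Strategy, delta: float, game: GameSpec
) -> PayoffDistribution:
    """Recalled payoff when updating is based on the average payoff of one
    interaction: a point mass at the expected payoff of that pairing."""
    return PayoffDistribution.point_mass(expected_payoff(s_focal, s_partner, delta, game))


def simulate_repeated_game(
    s_focal: Strategy,
    s_partner: Strategy,
    delta: float,
    game: GameSpec,
    rng: np.random.Generator,
) -> tuple[list[str], list[float], list[float]]:
    """Monte-Carlo play oracle: simulate one repeated game round by round.

    After each round the game continues with probability ``delta``, so the
    number of rounds is geometric with mean ``1 / (1 - delta)``.  Returns
    ``(joint_states, focal_payoffs, partner_payoffs)`` as per-round lists;
    joint states are strings like ``"CD"`` with the focal action first.
    """
    _check_delta(delta)
    f = s_focal.as_memory_one()
    p = s_partner.as_memory_one()
    f_probs = f.coop_probs()
    p_probs = p.coop_probs()[[0, 2, 1, 3]]  # partner's view, indexed by focal-view state
    pay_f = game.focal_payoffs
    pay_p = game.partner_payoffs
    names = ("CC", "CD", "DC", "DD")

    states: list[str] = []
    pf: list[float] = []
    pp: list[float] = []

    cf = rng.random() < f.y
    cp = rng.random() < p.y
    while True:
        state = (0 if cf else 2) + (0 if cp else 1)
        states.append(names[state])
        pf.append(float(pay_f[state]))
        pp.append(float(pay_p[state]))
        if rng.random() >= delta:
            break
        cf = rng.random() < f_probs[state]
        cp = rng.random() < p_probs[state]
    return states, pf, pp
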