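"""Rare-mutation evolutionary dynamics of repeated-game strategies.

In the small-mutation limit the population is monomorphic almost all of the
time: a single mutant either fixes or goes extinct before the next mutant
appears.  The evolutionary process therefore reduces to a chain over
resident strategies.  Each elementary step ("invasion attempt") draws one
mutant uniformly from the strategy space and replaces the resident with
probability equal to the mutant's fixation probability in the pairwise
comparison process.

Fixation probabilities come from the standard birth-death formula.  With
``j`` mutants among ``N`` players, the mutant count increases when a
resident learner is drawn together with a mutant role model and the
imitation succeeds::

    T_plus_j  = (N - j)/N * j/(N - 1) * phi_plus_j
    T_minus_j = j/N * (N - j)/(N - 1) * phi_minus_j
    rho = 1 / (1 + sum_{k=1}^{N-1} prod_{j=1}^{k} T_minus_j / T_plus_j)

The sampling prefactors cancel in the ratio, so only the imitation
probabilities ``phi`` matter.  Under perfect payoff memory ``phi`` is the
Fermi function of expected payoffs; under limited payoff memory it is the
expectation of the Fermi function over the two players' recalled-payoff
distributions (see :mod:`payoffmemory.payoff_memory`).  Products are
accumulated in log space so that strong selection does not overflow.

The hot paths (single-round recall, perfect memory, game-average recall)
are vectorized over batches of candidate mutants; larger recall windows
fall back to an exact but slower per-mutant route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np
from scipy.special import expit, logsumexp

from .games import GameSpec
from .payoff_memory import (
    MemoryModel,
    PopulationContext,
    effective_imitation_probability,
    fermi_probability,
)
from .repeated_game import (
    MemoryOneStrategy,
    ReactiveStrategy,
    Strategy,
    expected_payoff,
    simulate_repeated_game,
)

__all__ = [
    "EvoParams",
    "Trajectory",
    "InvasionResistance",
    "draw_random_strategy",
    "fixation_probability",
    "run_rare_mutation_chain",
    "average_cooperation_rate",
    "expected_mutants_until_replacement",
    "strategy_density_grid",
    "realized_update_step",
]

_PHI_FLOOR = 1e-300  # guards log() when the Fermi probability underflows


@dataclass(frozen=True)
class EvoParams:
    """Parameters of the rare-mutation imitation chain.

    ``T`` counts elementary steps of the embedded chain, i.e. invasion
    attempts (one uniform mutant plus one fixation lottery each).
    """

    N: int
    beta: float
    delta: float
    game: GameSpec
    memory: MemoryModel
    strategy_space: str = "reactive"
    T: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not (0.0 <= self.delta < 1.0):
            raise ValueError("delta must lie in [0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.strategy_space not in ("reactive", "memory_one"):
            raise ValueError("strategy_space must be 'reactive' or 'memory_one'")


@dataclass
class Trajectory:
    """Record of the embedded resident-to-resident chain.

    ``strategies`` holds one row of memory-one parameters
    ``(y, p_CC, p_CD, p_DC, p_DD)`` per resident epoch (reactive strategies
    are stored through their embedding, with the original ``(y, p, q)``
    recoverable as columns 0-2), ``sojourns`` the number of elementary steps
    each resident survived, and ``accepted`` whether the epoch ended with a
    successful invasion (the final epoch typically ends by truncation).
    """

    strategies: np.ndarray
    sojourns: np.ndarray
    accepted: np.ndarray
    params: EvoParams
    _coop_cache: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def total_steps(self) -> int:
        return int(self.sojourns.sum())

    def resident_objects(self) -> list[Strategy]:
        if self.params.strategy_space == "reactive":
            return [ReactiveStrategy(r[0], r[1], r[2]) for r in self.strategies]
        return [MemoryOneStrategy(*r) for r in self.strategies]

    def self_cooperation_rates(self) -> np.ndarray:
        """Discount-weighted self-play cooperation rate of each resident."""
        if self._coop_cache is None:
            w = _batched_final_state_dist(
                self.strategies, self.strategies, self.params.delta
            )
            self._coop_cache = w[:, 0] + w[:, 1]
        return self._coop_cache


class InvasionResistance(NamedTuple):
    """Expected number of uniform mutants needed to replace a resident."""

    expected_mutants: float
    standard_error: float
    mean_fixation_probability: float
    n_samples: int


# ---------------------------------------------------------------------------
# strategy sampling and parameter-array plumbing
# ---------------------------------------------------------------------------


def draw_random_strategy(space: str, rng: np.random.Generator) -> Strategy:
    """Uniform strategy draw: on [0,1]^3 for reactive strategies, on [0,1]^5
    for memory-one strategies."""
    if space == "reactive":
        y, p, q = rng.random(3)
        return ReactiveStrategy(y, p, q)
    if space == "memory_one":
        return MemoryOneStrategy(*rng.random(5))
    raise ValueError(f"unknown strategy space {space!r}")


def _draw_raw(space: str, n: int, rng: np.random.Generator) -> np.ndarray:
    dim = 3 if space == "reactive" else 5
    return rng.random((n, dim))


def _to_mem1_params(raw: np.ndarray, space: str) -> np.ndarray:
    """Map raw parameter rows to memory-one rows (y, pCC, pCD, pDC, pDD)."""
    raw = np.atleast_2d(raw)
    if space == "reactive":
        y, p, q = raw[:, 0], raw[:, 1], raw[:, 2]
        return np.stack([y, p, q, p, q], axis=1)
    return raw


def _strategy_to_raw(s: Strategy, space: str) -> np.ndarray:
    if space == "reactive":
        if not isinstance(s, ReactiveStrategy):
            raise ValueError("resident must be reactive in the reactive space")
        return np.array([s.y, s.p, s.q])
    m = s.as_memory_one()
    return np.array([m.y, m.p_cc, m.p_cd, m.p_dc, m.p_dd])


def _batched_final_state_dist(
    focal: np.ndarray, partner: np.ndarray, delta: float
) -> np.ndarray:
    """Final-round joint-state distributions for B strategy pairs at once.

    ``focal`` and ``partner`` are (B, 5) memory-one parameter arrays (or
    (B, 3) reactive, auto-embedded).  Returns a (B, 4) array over
    (CC, CD, DC, DD).
    """
    if focal.shape[1] == 3:
        focal = _to_mem1_params(focal, "reactive")
    if partner.shape[1] == 3:
        partner = _to_mem1_params(partner, "reactive")
    b_sz = focal.shape[0]
    x = focal[:, 1:5]  # focal coop prob per previous state
    z = partner[:, 1:5][:, [0, 2, 1, 3]]  # partner coop prob, focal-view states
    m = np.empty((b_sz, 4, 4))
    m[:, :, 0] = x * z
    m[:, :, 1] = x * (1 - z)
    m[:, :, 2] = (1 - x) * z
    m[:, :, 3] = (1 - x) * (1 - z)
    yf, yp = focal[:, 0], partner[:, 0]
    v0 = np.stack([yf * yp, yf * (1 - yp), (1 - yf) * yp, (1 - yf) * (1 - yp)], axis=1)
    a_t = np.eye(4)[None, :, :] - delta * np.transpose(m, (0, 2, 1))
    w = np.linalg.solve(a_t, (1 - delta) * v0[:, :, None])[:, :, 0]
    w = np.clip(w, 0.0, None)
    return w / w.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# fixation probabilities
# ---------------------------------------------------------------------------


def _rho_from_phi(log_phi_plus: np.ndarray, log_phi_minus: np.ndarray) -> np.ndarray:
    """Fixation probabilities from per-j imitation log-probabilities.

    Inputs have shape (B, N-1); the sampling prefactors of the birth-death
    chain cancel, leaving ``gamma_j = phi_minus_j / phi_plus_j``.
    """
    log_gamma = log_phi_minus - log_phi_plus
    cum = np.cumsum(log_gamma, axis=1)
    padded = np.concatenate([np.zeros((cum.shape[0], 1)), cum], axis=1)
    return np.exp(-logsumexp(padded, axis=1))


def _mixture_weights(N: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-j probabilities that a co-player is a mutant: ``lam`` for a
    resident focal player, ``kap`` for a mutant one (j = 1 .. N-1)."""
    j = np.arange(1, N)
    lam = j / (N - 1)
    kap = (j - 1) / (N - 1)
    return lam, kap


def _fixation_batch_fast(
    resident_raw: np.ndarray,
    mutants_raw: np.ndarray,
    params: EvoParams,
) -> np.ndarray:
    """Vectorized fixation probabilities for a batch of mutants.

    Supports perfect memory, single-round single-partner recall
    (last_rounds with k = m = 1) and game-average recall; other memory
    models go through the generic per-mutant route.
    """
    game = params.game
    delta, beta, N = params.delta, params.beta, params.N
    space = params.strategy_space
    res = _to_mem1_params(resident_raw[None, :], space)
    muts = _to_mem1_params(mutants_raw, space)
    b_sz = muts.shape[0]
    res_b = np.broadcast_to(res, (b_sz, 5))

    w_rr = _batched_final_state_dist(res, res, delta)  # (1, 4)
    w_rm = _batched_final_state_dist(res_b, muts, delta)
    w_mr = _batched_final_state_dist(muts, res_b, delta)
    w_mm = _batched_final_state_dist(muts, muts, delta)
    pay = game.focal_payoffs
    lam, kap = _mixture_weights(N)

    variant = params.memory.variant
    if variant == "perfect":
        pi_rr = float(w_rr[0] @ pay)
        pi_rm = w_rm @ pay
        pi_mr = w_mr @ pay
        pi_mm = w_mm @ pay
        pi_res = lam[None, :] * pi_rm[:, None] + (1 - lam)[None, :] * pi_rr
        pi_mut = kap[None, :] * pi_mm[:, None] + (1 - kap)[None, :] * pi_mr[:, None]
        diff = pi_mut - pi_res
        log_plus = _log_expit(beta * diff)
        log_minus = _log_expit(-beta * diff)
        return _rho_from_phi(log_plus, log_minus)

    if variant == "game_average":
        # point-mass recalled payoffs per co-player type
        pi_rr = float(w_rr[0] @ pay)
        pi_rm = w_rm @ pay
        pi_mr = w_mr @ pay
        pi_mm = w_mm @ pay

        def cross(pi_x, pi_y):
            return expit(beta * (pi_y - pi_x))

        c = {
            ("rm", "mm"): cross(pi_rm, pi_mm),
            ("rm", "mr"): cross(pi_rm, pi_mr),
            ("rr", "mm"): cross(pi_rr, pi_mm),
            ("rr", "mr"): cross(pi_rr, pi_mr),
            ("mm", "rm"): cross(pi_mm, pi_rm),
            ("mm", "rr"): cross(pi_mm, pi_rr),
            ("mr", "rm"): cross(pi_mr, pi_rm),
            ("mr", "rr"): cross(pi_mr, pi_rr),
        }
    else:  # last_rounds, k = m = 1: distributions over the four state payoffs
        f4 = expit(beta * (pay[None, :] - pay[:, None]))

        def cross_w(w_x, w_y):
            return np.einsum("ba,ac,bc->b", w_x, f4, w_y)

        w_rr_b = np.broadcast_to(w_rr, (b_sz, 4))
        c = {
            ("rm", "mm"): cross_w(w_rm, w_mm),
            ("rm", "mr"): cross_w(w_rm, w_mr),
            ("rr", "mm"): cross_w(w_rr_b, w_mm),
            ("rr", "mr"): cross_w(w_rr_b, w_mr),
            ("mm", "rm"): cross_w(w_mm, w_rm),
            ("mm", "rr"): cross_w(w_mm, w_rr_b),
            ("mr", "rm"): cross_w(w_mr, w_rm),
            ("mr", "rr"): cross_w(w_mr, w_rr_b),
        }

    def bilinear(a_mut, a_res, b_mut, b_res, wa, wb):
        # learner mixture weight wa on component `a_mut`, role model wb
        return (
            wa[None, :] * wb[None, :] * c[(a_mut, b_mut)][:, None]
            + wa[None, :] * (1 - wb)[None, :] * c[(a_mut, b_res)][:, None]
            + (1 - wa)[None, :] * wb[None, :] * c[(a_res, b_mut)][:, None]
            + (1 - wa)[None, :] * (1 - wb)[None, :] * c[(a_res, b_res)][:, None]
        )

    phi_plus = bilinear("rm", "rr", "mm", "mr", lam, kap)
    phi_minus = bilinear("mm", "mr", "rm", "rr", kap, lam)
    log_plus = np.log(np.clip(phi_plus, _PHI_FLOOR, None))
    log_minus = np.log(np.clip(phi_minus, _PHI_FLOOR, None))
    return _rho_from_phi(log_plus, log_minus)


def _log_expit(x: np.ndarray) -> np.ndarray:
    """log(expit(x)) without underflow: -log1p(exp(-x)) for x > 0, else
    x - log1p(exp(x))."""
    out = np.where(x > 0, -np.log1p(np.exp(-np.abs(x))), x - np.log1p(np.exp(-np.abs(x))))
    return out


def _has_fast_path(memory: MemoryModel) -> bool:
    if memory.variant in ("perfect", "game_average"):
        return True
    return memory.k == 1 and memory.m == 1


def _fixation_generic(
    resident: Strategy, mutant: Strategy, params: EvoParams
) -> float:
    """Exact per-j route through the public distribution machinery; handles
    any recall window (k, m)."""
    N = params.N
    log_plus = np.empty(N - 1)
    log_minus = np.empty(N - 1)
    for idx, j in enumerate(range(1, N)):
        ctx = PopulationContext(resident=resident, mutant=mutant, j=j, N=N)
        phi_p = effective_imitation_probability(
            "resident_member", "mutant_member", ctx, params.memory,
            params.beta, params.delta, params.game,
        )
        phi_m = effective_imitation_probability(
            "mutant_member", "resident_member", ctx, params.memory,
            params.beta, params.delta, params.game,
        )
        log_plus[idx] = math.log(max(phi_p, _PHI_FLOOR))
        log_minus[idx] = math.log(max(phi_m, _PHI_FLOOR))
    return float(_rho_from_phi(log_plus[None, :], log_minus[None, :])[0])


def fixation_probability(
    resident: Strategy, mutant: Strategy, params: EvoParams
) -> float:
    """Probability that a single mutant takes over a resident population of
    size ``N`` under the pairwise comparison process.

    Deterministic given strategies and parameters.  Equals ``1/N`` for a
    neutral mutant (identical strategy, or ``beta = 0``).
    """
    if _has_fast_path(params.memory):
        res_raw = _strategy_to_raw(resident, params.strategy_space)
        mut_raw = _strategy_to_raw(mutant, params.strategy_space)[None, :]
        return float(_fixation_batch_fast(res_raw, mut_raw, params)[0])
    return _fixation_generic(resident, mutant, params)


def _fixation_batch(
    resident_raw: np.ndarray, mutants_raw: np.ndarray, params: EvoParams
) -> np.ndarray:
    if _has_fast_path(params.memory):
        return _fixation_batch_fast(resident_raw, mutants_raw, params)
    res = _raw_to_strategy(resident_raw, params.strategy_space)
    out = np.empty(mutants_raw.shape[0])
    for i, row in enumerate(mutants_raw):
        out[i] = _fixation_generic(
            res, _raw_to_strategy(row, params.strategy_space), params
        )
    return out


def _raw_to_strategy(raw: np.ndarray, space: str) -> Strategy:
    if space == "reactive":
        return ReactiveStrategy(*raw[:3])
    return MemoryOneStrategy(*raw[:5])


# ---------------------------------------------------------------------------
# the embedded chain
# ---------------------------------------------------------------------------

_BLOCK = 256  # invasion attempts evaluated per batch; fixed for determinism


def run_rare_mutation_chain(
    params: EvoParams,
    initial_resident: Optional[Strategy] = None,
    progress: Optional["Callable[[int], None]"] = None,
) -> Trajectory:
    """Run the embedded rare-mutation chain for ``params.T`` invasion
    attempts and return the resident :class:`Trajectory`.

    Each attempt draws a uniform mutant and replaces the resident with
    probability :func:`fixation_probability`.  The process is ergodic for
    finite selection strength, so long-run summaries do not depend on the
    initial resident (which defaults to ALLD).  ``progress``, if given, is
    called with the running step count after each evaluated batch.
    """
    space = params.strategy_space
    if initial_resident is None:
        initial_resident = (
            ReactiveStrategy(0.0, 0.0, 0.0)
            if space == "reactive"
            else MemoryOneStrategy(0.0, 0.0, 0.0, 0.0, 0.0)
        )
    children = np.random.SeedSequence(params.seed).spawn(2)
    mut_rng = np.random.Generator(np.random.PCG64(children[0]))
    acc_rng = np.random.Generator(np.random.PCG64(children[1]))

    resident = _strategy_to_raw(initial_resident, space)
    epochs: list[np.ndarray] = []
    sojourns: list[int] = []
    accepted: list[bool] = []

    steps_done = 0
    current_sojourn = 0
    while steps_done < params.T:
        block = min(_BLOCK, params.T - steps_done)
        mutants = _draw_raw(space, block, mut_rng)
        u = acc_rng.random(block)
        rho = _fixation_batch(resident, mutants, params)
        hits = np.nonzero(u < rho)[0]
        if hits.size:
            i = int(hits[0])
            current_sojourn += i + 1
            steps_done += i + 1
            epochs.append(resident.copy())
            sojourns.append(current_sojourn)
            accepted.append(True)
            resident = mutants[i].copy()
            current_sojourn = 0
        else:
            current_sojourn += block
            steps_done += block
        if progress is not None:
            progress(steps_done)
    epochs.append(resident.copy())
    sojourns.append(current_sojourn)
    accepted.append(False)
    # drop a zero-length final epoch (replacement on the very last step)
    if sojourns[-1] == 0:
        epochs.pop()
        sojourns.pop()
        accepted.pop()
    return Trajectory(
        strategies=_to_mem1_params(np.array(epochs), space),
        sojourns=np.array(sojourns, dtype=np.int64),
        accepted=np.array(accepted, dtype=bool),
        params=params,
    )


def average_cooperation_rate(
    traj: Trajectory, delta: Optional[float] = None, burn_in: float = 0.0
) -> float:
    """Sojourn-weighted mean self-play cooperation rate over the trajectory.

    ``burn_in`` is the fraction of initial steps discarded before averaging
    (the chain is ergodic; burn-in reduces initial-condition bias in short
    runs).
    """
    if traj.sojourns.size == 0:
        raise ValueError("empty trajectory")
    if not (0.0 <= burn_in < 1.0):
        raise ValueError("burn_in must be in [0, 1)")
    if delta is not None and delta != traj.params.delta:
        w = _batched_final_state_dist(traj.strategies, traj.strategies, delta)
        rates = w[:, 0] + w[:, 1]
    else:
        rates = traj.self_cooperation_rates()
    weights = traj.sojourns.astype(float).copy()
    skip = burn_in * weights.sum()
    if skip > 0:
        cum = np.cumsum(weights)
        consumed = np.minimum(np.maximum(skip - (cum - weights), 0.0), weights)
        weights = weights - consumed
    total = weights.sum()
    if total <= 0:
        raise ValueError("burn-in removed the entire trajectory")
    return float((rates * weights).sum() / total)


def expected_mutants_until_replacement(
    resident: Strategy,
    params: EvoParams,
    n_samples: int,
    rng: np.random.Generator,
) -> InvasionResistance:
    """Expected number of uniformly drawn mutants until the resident is
    replaced, estimated as ``1 / mean(rho)`` over ``n_samples`` mutants.

    Each mutant independently fixes with its own probability, so the number
    of attempts until the first success is geometric with success rate
    ``E[rho]``; its mean is the reciprocal.  The standard error of the count
    follows from the delta method.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    res_raw = _strategy_to_raw(resident, params.strategy_space)
    rhos = np.empty(n_samples)
    chunk = 8192
    for start in range(0, n_samples, chunk):
        stop = min(start + chunk, n_samples)
        mutants = _draw_raw(params.strategy_space, stop - start, rng)
        rhos[start:stop] = _fixation_batch(res_raw, mutants, params)
    mean_rho = float(rhos.mean())
    se_mean = float(rhos.std(ddof=1) / math.sqrt(n_samples)) if n_samples > 1 else math.inf
    return InvasionResistance(
        expected_mutants=1.0 / mean_rho,
        standard_error=se_mean / mean_rho**2,
        mean_fixation_probability=mean_rho,
        n_samples=n_samples,
    )


def strategy_density_grid(traj: Trajectory, bins: int = 50) -> np.ndarray:
    """Sojourn-weighted 2-D histogram of resident strategies, normalized to
    total mass one.

    The two binned coordinates are the conditional cooperation probabilities
    after a partner's cooperation and defection — ``(p, q)`` for reactive
    strategies (the opening move is omitted, as it is nearly irrelevant for
    delta close to 1) and ``(p_CC, p_CD)`` for memory-one strategies.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    p = traj.strategies[:, 1]
    q = traj.strategies[:, 2]
    hist, _, _ = np.histogram2d(
        p, q, bins=bins, range=[[0, 1], [0, 1]], weights=traj.sojourns.astype(float)
    )
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# agent-based oracle
# ---------------------------------------------------------------------------


def _sample_recalled_payoff(
    focal_idx: int,
    population: Sequence[Strategy],
    memory: MemoryModel,
    delta: float,
    game: GameSpec,
    rng: np.random.Generator,
) -> float:
    focal = population[focal_idx]
    others = [s for i, s in enumerate(population) if i != focal_idx]
    if memory.variant == "perfect":
        return float(
            np.mean([expected_payoff(focal, o, delta, game) for o in others])
        )
    if memory.variant == "game_average":
        partner = others[rng.integers(len(others))]
        return expected_payoff(focal, partner, delta, game)
    draws = []
    for _ in range(memory.m):
        partner = others[rng.integers(len(others))]
        _, payoffs, _ = simulate_repeated_game(focal, partner, delta, game, rng)
        window = payoffs[-memory.k:]
        draws.append(float(np.mean(window)))
    return float(np.mean(draws))


def realized_update_step(
    population: list[Strategy],
    memory: MemoryModel,
    beta: float,
    delta: float,
    game: GameSpec,
    rng: np.random.Generator,
) -> list[Strategy]:
    """One elementary imitation event with payoffs sampled by actually
    playing games (agent-based oracle for the analytic imitation
    probabilities).

    A random learner compares its sampled recalled payoff with that of a
    random role model and copies the role model's strategy with the Fermi
    probability.  Returns the updated population (a new list).
    """
    n = len(population)
    learner = int(rng.integers(n))
    rm = int(rng.integers(n - 1))
    if rm >= learner:
        rm += 1
    pi_l = _sample_recalled_payoff(learner, population, memory, delta, game, rng)
    pi_rm = _sample_recalled_payoff(rm, population, memory, delta, game, rng)
    new_pop = list(population)
    if rng.random() < fermi_probability(pi_l, pi_rm, beta):
        new_pop[learner] = population[rm]
    return new_pop
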