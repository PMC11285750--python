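# Methods

## Model

Two time scales are modelled.  On the short (game) time scale, pairs of
players from a well-mixed population of size `N` play a repeated two-player
game.  Each round both players choose cooperate (C) or defect (D); after
each round the game continues with a fixed probability `δ ∈ [0, 1)`, so the
number of rounds is geometric with mean `1/(1-δ)`.  Two stage games are
supported: the donation game (cooperating pays `c` to give the partner `b`,
`0 < c < b`) and the snowdrift game (the benefit `b` arrives if anyone
cooperates; the cost is `c` for a lone cooperator, `c/2` each under mutual
cooperation).  Strategies are *reactive* triples `(y, p, q)` — opening
cooperation probability, and cooperation probabilities after the partner's
C or D — or *memory-one* quintuples conditioning on both players' previous
actions.  Joint actions are ordered `(CC, CD, DC, DD)`, focal player first;
a reactive strategy embeds into memory-one space with `p_CC = p_DC = p`,
`p_CD = p_DD = q`, and the embedding reproduces all quantities exactly
(tested).

For a strategy pair the joint action follows a 4-state Markov chain with
transition matrix `M` built from the two conditional cooperation
probabilities.  Because the final round index `T` satisfies
`P(T = t) = (1-δ)δ^t`, the joint action of the *final* round is distributed
as

    w = (1-δ) · v₀ · (I - δM)⁻¹,

the discount-weighted mixture of per-round distributions (`v₀` = outer
product of the opening probabilities).  All per-pair quantities derive from
`w`: the expected (normalized discounted) payoff `π = w·u`, the cooperation
rate `w(CC) + w(CD)`, and the last-round payoff distribution — the image of
`w` under the payoff function.  The identity `E[u_T] = (1-δ) Σ δ^t E[u_t]`
makes the realized last-round payoff an unbiased estimator of the expected
payoff; the test suite asserts it to 1e-10 on random instances.

On the long (evolutionary) time scale, strategies spread by social
learning: a random learner compares its payoff `π_L` with a random role
model's `π_RM` and imitates with the Fermi probability
`φ = 1/(1 + e^{-β(π_RM - π_L)})`, selection strength `β ≥ 0`.  The memory
model decides what `π_L` and `π_RM` are:

- **perfect** — deterministic expected payoff averaged over all `N-1`
  co-players (the classical setup);
- **last_rounds(k, m)** — the mean of the realized payoffs from the last
  `k` rounds against each of `m` recently encountered co-players (the
  limited-memory model; `k = m = 1` is the extreme single-round case);
- **game_average** — the per-round average payoff of a single repeated game
  against one random co-player.

## Recalled-payoff distributions

For the stochastic memories, the payoff a player brings to a comparison is
a random variable with finite support.  In a population with `j` mutants,
the co-player of a focal mutant is itself a mutant with probability
`(j-1)/(N-1)` (a player is never its own partner), so the one-draw recall
distribution is the corresponding mixture of per-co-player window
distributions; for `m ≥ 2` the recall is the mean of `m` independent such
draws (co-players sampled independently with replacement — an `O(1/N)`
approximation to sampling distinct partners, chosen as the simplest
contract consistent with a well-mixed population).  Learner and role-model
draws are treated as independent; the `~1/(N-1)` probability that the two
just played each other is ignored on the same grounds.

The last-`k`-rounds window distribution is computed exactly for any `k`:
games lasting at least `k` rounds contribute the `4^k` state paths started
from `w` (the state `k-1` rounds before the end is `w`-distributed, with
total mass `δ^{k-1}`), and the finitely many shorter games (mass
`1 - δ^{k-1}`) are enumerated directly, averaging over the rounds that
exist.  No series truncation is involved; support values closer than 1e-9
are merged.  The `game_average` recall is implemented as a point mass at
the expected payoff of the sampled pairing: the realized within-game
average converges to it as δ → 1, which is the regime in which the
associated threshold `1 - c/b` is quoted, and the expectation version keeps
the distribution support finite at any δ.  Multi-round recall aggregates by
*mean* rather than sum; under strong selection the two are equivalent, and
the mean keeps payoffs on the stage-game scale at finite β.

The effective imitation probability is the exact double sum of the Fermi
function over the two product supports.  Useful limits, all asserted in
tests: `β = 0` gives 1/2 regardless of payoffs; as `β → ∞` it tends to
`P(π_RM > π_L) + ½·P(tie)`; for `β → 0` it agrees with the Fermi function
of the expected payoffs to first order in β (weak-selection equivalence of
the memory models).

## Stochastic stability and thresholds

A fully cooperative resident GTFT `= (1, 1, q)` is called stochastically
stable against ALLD if, in the large-`N`, strong-selection limit, a single
ALLD mutant is more likely to imitate the residents than vice versa.  The
large-`N` limit is taken exactly (co-players of both the mutant and a
resident are residents with probability one), not as a large finite `N`.
For perfect memory the criterion compares expected payoffs; for stochastic
memories it compares `P(mutant recall > resident recall)` with the reverse
probability, ties contributing equally to both sides and hence cancelling.
Equality is treated as *unstable* (the analytic conditions are strict
inequalities).  This yields `q < 1 - c/(δb)` (perfect, donation),
`q < 1 - 1/(2δ)` (single-round recall, donation *and* snowdrift — only the
payoff ordering matters, and the one ordering difference between the two
games is irrelevant to this comparison), `q < 1 - c/(2δb)` (perfect,
snowdrift), `q < √2/2` for two recalled one-shot payoffs (`k=2,m=1` or
`k=1,m=2`, donation, `b > 2c`, δ → 1) and `q < 1 - c/b` (game average,
δ → 1).

`threshold_bisection` recovers any threshold numerically: it verifies
stability at `q = 0` (otherwise infeasible) and instability at `q = 1`,
then bisects for 60 iterations (bracket width 1e-18 nominal; agreement
with the closed forms is asserted to 1e-6 over a `(b, c, δ)` grid).  The
closed-form evaluator refuses combinations without a derived formula and
reports δ-near-1 formulas only for `δ ≥ 0.999`, directing callers to
bisection otherwise.  "δ → 1" is represented as `δ = 1 - 1e-6` throughout;
δ = 1 itself is rejected so `(I - δM)` stays invertible.

## Rare-mutation evolutionary dynamics

Mutations are taken to be rare: the population is monomorphic between
invasion attempts, and evolution reduces to the embedded chain whose
elementary step draws one mutant uniformly from the strategy cube (`[0,1]³`
reactive, `[0,1]⁵` memory-one, opening move included) and accepts it with
its fixation probability.  Fixation follows the birth–death formula with
per-mutant-count imitation probabilities; the learner/role-model sampling
prefactors cancel in the ratio, so only
`γ_j = φ⁻_j / φ⁺_j` enters, accumulated in log space (log-sum-exp for the
final sum) so that β up to at least 10 cannot overflow.  For perfect
memory, single-round recall and game-average recall the whole computation
is vectorized over batches of mutants: the four pairwise final-round state
distributions are obtained from batched 4×4 linear solves, the Fermi cross
terms between the (at most four-point) per-co-player distributions are
precomputed once per mutant, and the per-`j` mixture weights make `φ±_j`
bilinear in them.  Larger windows (`k ≥ 2` or `m ≥ 2`) use an exact
per-mutant route through the public distribution machinery.

The chain itself evaluates proposals in fixed-size batches of 256 attempts
(proposals after an accepted invasion are discarded and redrawn), which
changes nothing statistically and keeps runs bit-reproducible for a given
seed; the master seed spawns separate named substreams for mutant draws and
acceptance lotteries.  One "time step" is one invasion attempt.  The
cooperation rate of a trajectory is the sojourn-weighted mean of each
resident's discounted self-play cooperation rate (transient mixed states
carry no weight in the rare-mutation limit), with the first 10% of steps
discarded as burn-in in reported summaries to suppress the initial-condition
bias of shortened runs (the chain starts at ALLD by default and is ergodic).
Invasion resistance of a resident is estimated as `1 / mean(ρ)` over
uniform mutants — the waiting time to the first success of independent
trials with success rate `E[ρ]` is geometric — with a delta-method standard
error.

An agent-based oracle (`realized_update_step`) implements the update
process literally — every recalled payoff sampled by actually playing
games — and the tests check the analytic fixation probabilities and
imitation frequencies against it within three standard errors.

## Problem sizes and numerical defaults

Reported chain quantities use 10⁶–2×10⁶ invasion attempts per condition
(the acceptance script: 2×10⁶ for the four headline cooperation rates, 10⁶
per benefit in the plateau scan) and 10⁵ mutants for invasion counts;
convergence was checked by comparing 4×10⁵-, 10⁶- and 2×10⁶-step runs and
multiple seeds, which agree within ~2 percentage points.  Baseline
parameters are `N = 100`, `c = 1`, `δ = 0.999`, `β = 1` (the plateau scan
uses `δ = 0.99`).  Distribution supports are merged at 1e-9; probability
normalization is enforced at 1e-12; the stability boundary uses strict
comparison with a 1e-15 guard.

## Known limitations

- The chain length used here is below the 10⁷-step scale of the original
  simulations; cooperation-rate estimates carry a seed-to-seed spread of
  roughly ±2 percentage points at 10⁶ steps.  One consequence: the
  limited-memory cooperation plateau across `b ∈ {5, 7, 10}` at `δ = 0.99`
  converges to ~43–46% here, a few points below the ~50% sometimes quoted
  for that regime, while the `δ = 0.999` quantities agree within a point.
- Positive mutation rates, structured populations, strategy inference from
  observed play, and coevolving memory capacity are out of scope.
- The independence and with-replacement approximations above introduce
  `O(1/N)` errors at finite `N`; stability analysis is exact only in the
  `N → ∞` limit it targets.
- The synthetic inputs are the model's own primitives (uniform strategy
  draws, geometric game lengths); no feature of empirical behavioural data
  (noise in execution, non-stationary strategies) is emulated, so passing
  tests validate the mathematics, not behavioural realism.
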