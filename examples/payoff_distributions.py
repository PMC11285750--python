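"""What payoff does a defector remember from its last round?

A single ALLD mutant in a GTFT(q) population receives the temptation payoff
b whenever the resident happens to cooperate in the final round (probability
1 - delta + delta*q) and the punishment payoff 0 otherwise.  The mean of
this last-round distribution is exactly the discounted expected payoff —
the realized last-round payoff is an unbiased estimator of it.
"""

from payoffmemory import (
    ALLD,
    build_donation_game,
    expected_payoff,
    gtft,
    last_k_payoff_distribution,
    last_round_payoff_distribution,
)

game = build_donation_game(3, 1)
delta, q = 0.9, 0.3
resident = gtft(q)

dist = last_round_payoff_distribution(ALLD, resident, delta, game)
print(f"ALLD vs GTFT({q}) at delta={delta}: last-round payoff distribution")
for value, prob in zip(dist.support, dist.probs):
    print(f"  payoff {value:4.1f}  with probability {prob:.3f}")
print(f"  mean            = {dist.mean():.4f}")
print(f"  expected payoff = {expected_payoff(ALLD, resident, delta, game):.4f}")

dist2 = last_k_payoff_distribution(ALLD, resident, 1 - 1e-6, game, 2)
print(f"\nmean payoff over the last two rounds (delta -> 1):")
for value, prob in zip(dist2.support, dist2.probs):
    print(f"  payoff {value:4.1f}  with probability {prob:.3f}")
print(
    "\nThe two-round average takes the middle value b/2 with probability"
    f"\n2q(1-q) = {2*q*(1-q):.3f}: averaging windows thin out the lucky tail that"
    "\nmakes defectors look good in single-round comparisons."
)
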