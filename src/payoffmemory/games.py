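"""One-shot stage games used as the round payoff structure of the repeated game.

Two social dilemmas are supported:

* the **donation game**, a Prisoner's Dilemma in which a cooperator pays a
  cost ``c`` to confer a benefit ``b`` on the partner (``0 < c < b``), and
* the **snowdrift game**, in which the benefit ``b`` accrues to both players
  if at least one cooperates, with the cost shared (``c/2`` each) under
  mutual cooperation and borne alone (``c``) by a lone cooperator.

Joint actions are ordered ``(CC, CD, DC, DD)`` with the first letter the
focal player's action; this ordering is fixed package-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GameSpec",
    "build_donation_game",
    "build_snowdrift_game",
    "JOINT_STATES",
]

#: Joint-action ordering used everywhere: focal player's action first.
JOINT_STATES: tuple[str, ...] = ("CC", "CD", "DC", "DD")


@dataclass(frozen=True)
class GameSpec:
    """A symmetric 2x2 stage game, viewed from the focal player.

    Attributes
    ----------
    name : str
        ``"donation"`` or ``"snowdrift"``.
    b, c : float
        Benefit and cost of cooperation, in payoff units, with ``0 < c < b``.
    focal_payoffs : numpy.ndarray
        Focal player's payoff in each joint state, ordered ``(CC, CD, DC, DD)``.
    """

    name: str
    b: float
    c: float
    focal_payoffs: np.ndarray = field(repr=False)

    def payoff(self, own: str, partner: str) -> float:
        """Focal payoff for one round given both actions (``"C"`` or ``"D"``)."""
        return float(self.focal_payoffs[JOINT_STATES.index(own + partner)])

    @property
    def partner_payoffs(self) -> np.ndarray:
        """Partner's payoff per joint state; the game is symmetric, so this
        is the focal payoff vector with the CD/DC entries swapped."""
        return self.focal_payoffs[[0, 2, 1, 3]]


def _check_bc(b: float, c: float) -> None:
    if not (0.0 < c < b):
        raise ValueError(f"need 0 < c < b, got b={b}, c={c}")


def build_donation_game(b: float, c: float) -> GameSpec:
    """Donation game: cooperation gives ``b`` to the partner at own cost ``c``.

    Payoffs are ``(b-c, -c, b, 0)`` over ``(CC, CD, DC, DD)``; for
    ``0 < c < b`` the Prisoner's-Dilemma ordering ``b > b-c > 0 > -c`` holds.
    """
    _check_bc(b, c)
    return GameSpec(
        name="donation",
        b=float(b),
        c=float(c),
        focal_payoffs=np.array([b - c, -c, b, 0.0], dtype=float),
    )


def build_snowdrift_game(b: float, c: float) -> GameSpec:
    """Snowdrift game: the benefit arrives if anyone cooperates; cooperators
    split the cost when both cooperate.

    Payoffs are ``(b-c/2, b-c, b, 0)`` over ``(CC, CD, DC, DD)``; for
    ``0 < c < b`` the ordering ``b > b-c/2 > b-c > 0`` holds, so the sucker's
    payoff exceeds the punishment payoff.
    """
    _check_bc(b, c)
    return GameSpec(
        name="snowdrift",
        b=float(b),
        c=float(c),
        focal_payoffs=np.array([b - c / 2.0, b - c, b, 0.0], dtype=float),
    )
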