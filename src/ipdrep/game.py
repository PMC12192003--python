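"""One-shot Prisoner's Dilemma payoffs between reputation-parameterised agents.

Each agent cooperates with probability equal to its own reputation,
independently of its opponent. The expected payoff of player 1 is therefore
bilinear in the two reputations:

    G1(q1, q2) = q1 [q2 R + (1 - q2) S] + (1 - q1) [q2 T + (1 - q2) P]

and by symmetry G2(q1, q2) = G1(q2, q1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import ReputationDistribution

__all__ = [
    "PayoffMatrix",
    "DEFAULT_PAYOFFS",
    "ModelParams",
    "expected_game_payoff",
    "realized_payoffs",
]


@dataclass(frozen=True)
class PayoffMatrix:
    """The four Prisoner's Dilemma payoffs.

    T (temptation) > R (reward) > P (punishment) > S (sucker), with
    2R > T + S so that mutual cooperation beats alternating exploitation.
    These orderings are enforced unless ``strict=False``, which admits
    other social-dilemma matrices (Snowdrift, Stag Hunt) without relabeling.
    """

    T: float = 5.0
    R: float = 3.0
    P: float = 1.0
    S: float = 0.0
    strict: bool = True

    def __post_init__(self) -> None:
        if self.strict:
            if not (self.T > self.R > self.P > self.S):
                raise ValueError(
                    f"not a Prisoner's Dilemma: need T > R > P > S, got "
                    f"T={self.T}, R={self.R}, P={self.P}, S={self.S}"
                )
            if not (2 * self.R > self.T + self.S):
                raise ValueError(
                    f"not a Prisoner's Dilemma: need 2R > T + S, got "
                    f"2*{self.R} <= {self.T} + {self.S}"
                )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.T, self.R, self.P, self.S)


DEFAULT_PAYOFFS = PayoffMatrix()


@dataclass(frozen=True, eq=False)
class ModelParams:
    """Full analytic model instance: subgroup size, density, payoffs.

    ``n`` is the number of candidates sampled when choosing the second
    player; the one with the highest reputation among the ``n`` is taken.
    """

    n: int
    dist: ReputationDistribution
    payoffs: PayoffMatrix = field(default_factory=PayoffMatrix)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"subgroup size n must be >= 1, got {self.n}")


def _check_reputation(q, name: str) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return q


def expected_game_payoff(q1, q2, payoffs: PayoffMatrix = DEFAULT_PAYOFFS):
    """Expected payoff G1(q1, q2) of player 1; vectorised in both arguments."""
    q1 = _check_reputation(q1, "q1")
    q2 = _check_reputation(q2, "q2")
    T, R, P, S = payoffs.as_tuple()
    return q1 * (q2 * R + (1 - q2) * S) + (1 - q1) * (q2 * T + (1 - q2) * P)


_PAYOFF_TABLE = {
    ("C", "C"): lambda p: (p.R, p.R),
    ("C", "D"): lambda p: (p.S, p.T),
    ("D", "C"): lambda p: (p.T, p.S),
    ("D", "D"): lambda p: (p.P, p.P),
}


def realized_payoffs(
    action1: str, action2: str, payoffs: PayoffMatrix = DEFAULT_PAYOFFS
) -> tuple[float, float]:
    """Payoff pair for one realised game; actions are 'C' or 'D'."""
    try:
        return _PAYOFF_TABLE[(action1, action2)](payoffs)
    except KeyError:
        raise ValueError(f"actions must be 'C' or 'D', got ({action1!r}, {action2!r})") from None
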