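"""Circular-dominance matching games (rock-paper-scissors and variants).

The games modeled here have ``n`` actions arranged on a circle: action ``i``
beats action ``i - 1`` (mod ``n``) and is beaten by action ``i + 1`` (mod
``n``), so dominance is circular and nontransitive.  Actions are 0-indexed
internally; on-screen labels ``1..n`` map to indices ``0..n-1``.

Two payoff conventions are supported: the zero-sum scheme (win +1, loss -1,
tie 0) and a configurable non-zero-sum scheme (default win +1, loss 0,
tie 0).  Agents may additionally weight losses by a factor ``lambda``
(:func:`scale_losses`), which rescales only the -1 entries of their internal
payoff matrix; realized game outcomes always use the unscaled matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GameSpec",
    "PayoffMatrix",
    "build_payoff_matrix",
    "scale_losses",
    "round_outcome",
]

#: canonical action names for the 3-action game, index order
RPS_ACTIONS = ("rock", "paper", "scissors")


@dataclass(frozen=True)
class GameSpec:
    """Definition of a circular matching game.

    Parameters
    ----------
    n_actions:
        Number of available actions (>= 3).
    zero_sum:
        If True, win/loss/tie pay +1/-1/0.  If False, the payoffs in
        ``nonzero_sum_payoffs`` (win, loss, tie) are used instead.
    variant_label:
        Free-text label for bookkeeping.
    nonzero_sum_payoffs:
        (win, loss, tie) payoffs for the non-zero-sum variant.
    """

    n_actions: int = 3
    zero_sum: bool = True
    variant_label: str = "rps"
    nonzero_sum_payoffs: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_actions < 3:
            raise ValueError(
                f"a circular game needs at least 3 actions, got {self.n_actions}"
            )


@dataclass(frozen=True)
class PayoffMatrix:
    """Payoff matrix Pi: ``entries[i, j]`` pays the row player choosing ``i``
    against a column player choosing ``j``.

    ``lambda_applied`` records the loss weight already folded in (None for an
    unscaled matrix).
    """

    entries: np.ndarray
    lambda_applied: float | None = None
    spec: GameSpec | None = field(default=None, compare=False)

    @property
    def n_actions(self) -> int:
        return self.entries.shape[0]


def build_payoff_matrix(spec: GameSpec) -> PayoffMatrix:
    """Build the payoff matrix from the circular dominance rule.

    Action ``i`` beats ``j`` iff ``i == (j + 1) mod n``: picking the number
    one step ahead of the opponent's number wins the round.
    """
    n = spec.n_actions
    pi = np.zeros((n, n))
    win, loss, tie = (1.0, -1.0, 0.0) if spec.zero_sum else spec.nonzero_sum_payoffs
    pi[:] = tie
    for j in range(n):
        pi[(j + 1) % n, j] = win
        pi[j, (j + 1) % n] = loss
    np.fill_diagonal(pi, 0.0)
    return PayoffMatrix(entries=pi, lambda_applied=None, spec=spec)


def scale_losses(pi: PayoffMatrix, lam: float) -> PayoffMatrix:
    """Reweight losses: every -1 entry becomes ``-lam``; all else unchanged.

    This is the agent-internal distortion of the payoff matrix; it enters the
    agent's recursive reasoning and valuation, never the logged outcomes.
    """
    if lam < 0:
        raise ValueError(f"loss weight lambda must be >= 0, got {lam}")
    entries = pi.entries.copy()
    entries[pi.entries == -1.0] = -lam
    return PayoffMatrix(entries=entries, lambda_applied=lam, spec=pi.spec)


def round_outcome(
    a_self: int, a_opp: int, pi: PayoffMatrix
) -> tuple[float, float]:
    """Realized payoffs (self, opponent) for one round.

    Uses the same matrix from both perspectives (the game is symmetric):
    the opponent's payoff is ``entries[a_opp, a_self]``.
    """
    n = pi.n_actions
    if not (0 <= a_self < n) or not (0 <= a_opp < n):
        raise IndexError(
            f"action out of range for {n}-action game: ({a_self}, {a_opp})"
        )
    return float(pi.entries[a_self, a_opp]), float(pi.entries[a_opp, a_self])
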