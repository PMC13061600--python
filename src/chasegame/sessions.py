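"""Session logs: per-trial records of repeated-game play, grouped in blocks.

A :class:`SessionLog` holds one participant's data: an ordered list of blocks,
each with an opponent description and aligned arrays of own actions, opponent
actions and realized payoffs.  All model state (attractions, beliefs) resets
at block boundaries, so the block structure is part of the data contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .game import GameSpec

__all__ = ["BlockRecord", "SessionLog"]


@dataclass
class BlockRecord:
    """One block of consecutive trials against a single opponent."""

    actions_self: np.ndarray
    actions_opp: np.ndarray
    payoffs_self: np.ndarray
    payoffs_opp: np.ndarray
    opponent: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.actions_self = np.asarray(self.actions_self, dtype=np.int64)
        self.actions_opp = np.asarray(self.actions_opp, dtype=np.int64)
        self.payoffs_self = np.asarray(self.payoffs_self, dtype=float)
        self.payoffs_opp = np.asarray(self.payoffs_opp, dtype=float)
        lens = {
            len(self.actions_self),
            len(self.actions_opp),
            len(self.payoffs_self),
            len(self.payoffs_opp),
        }
        if len(lens) != 1:
            raise ValueError("block arrays have inconsistent lengths")

    @property
    def n_trials(self) -> int:
        return len(self.actions_self)


@dataclass
class SessionLog:
    """All blocks of one participant in one game."""

    participant: str
    game: GameSpec
    blocks: list[BlockRecord]
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten to (actions_self, actions_opp, block_ids) int64 arrays."""
        acts_s = np.concatenate([b.actions_self for b in self.blocks])
        acts_o = np.concatenate([b.actions_opp for b in self.blocks])
        ids = np.concatenate(
            [np.full(b.n_trials, i, dtype=np.int64) for i, b in enumerate(self.blocks)]
        )
        return acts_s.astype(np.int64), acts_o.astype(np.int64), ids
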