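"""Playable agents: generative wrappers around the model step functions.

Every agent exposes ``reset()`` (fresh block state), ``policy()`` (current
action probabilities) and ``observe(own, opp)`` (state update after a
trial).  Policies at trial t depend only on history through t-1, so the
simulator can sample both sides simultaneously without information leaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import baselines as bl
from .chase import (
    AttractionPair,
    ChaseParams,
    chase_step,
    init_chase_state,
    level_policy,
    scaled_matrix,
    update_attractions,
)
from .game import GameSpec, build_payoff_matrix

__all__ = [
    "OpponentSpec",
    "ChaseAgent",
    "FixedLevelOpponent",
    "UniformAgent",
    "RLAgent",
    "EWAAgent",
    "STEWAAgent",
    "ToMkAgent",
    "make_agent",
]


@dataclass(frozen=True)
class OpponentSpec:
    """Fixed-level artificial opponent (no adaptive belief updating).

    The opponent uses the same attraction learning and recursive reasoning
    as a CHASE agent but is pinned to one sophistication level; its noise is
    parameterized by an inverse temperature and a lapse rate (probability of
    a uniformly random action).  Defaults are chosen so that a low-noise
    kappa=3 CHASE agent earns positive scores against all three levels.
    """

    level: int = 0
    beta_opp: float = 6.0
    lapse: float = 0.1
    alpha_opp: float = 0.3

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError(f"level must be >= 0, got {self.level}")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError(f"lapse must be in [0, 1], got {self.lapse}")

    def to_dict(self) -> dict:
        return {
            "kind": "fixed_level",
            "level": self.level,
            "beta_opp": self.beta_opp,
            "lapse": self.lapse,
            "alpha_opp": self.alpha_opp,
        }


class ChaseAgent:
    """Adaptive CHASE player."""

    def __init__(self, params: ChaseParams, game: GameSpec):
        self.params = params
        self.game = game
        self._pi = scaled_matrix(game, params.lam)
        self.reset()

    def reset(self) -> None:
        self.state = init_chase_state(self.game.n_actions, self.params.kappa)

    def policy(self) -> np.ndarray:
        from .chase import integrated_policy

        preds = np.stack(
            [
                level_policy(
                    k,
                    self.state.attractions,
                    "opponent_prediction",
                    self._pi,
                    self.params.beta,
                )
                for k in range(self.params.kappa)
            ]
        )
        own, _ = integrated_policy(
            self.state.beliefs.b, preds, self._pi, self.params.beta
        )
        return own

    def observe(self, own: int, opp: int) -> None:
        self.state, self.last_derivatives = chase_step(
            self.state, own, opp, self.params, self._pi
        )


class FixedLevelOpponent:
    """Artificial opponent: CHASE learning rule at a fixed level, with lapses.

    Attractions are maintained from the opponent's own perspective (its
    ``a_self`` is its own action history).  A level-0 opponent therefore
    prefers, and repeats, actions it played in the recent past.
    """

    def __init__(self, spec: OpponentSpec, game: GameSpec):
        self.spec = spec
        self.game = game
        self._pi = build_payoff_matrix(game).entries
        self.reset()

    def reset(self) -> None:
        self.attr = AttractionPair.uniform(self.game.n_actions)

    def policy(self) -> np.ndarray:
        n = self.game.n_actions
        base = level_policy(
            self.spec.level, self.attr, "self_play", self._pi, self.spec.beta_opp
        )
        return (1.0 - self.spec.lapse) * base + self.spec.lapse / n

    def observe(self, own: int, opp: int) -> None:
        self.attr = AttractionPair(
            a_self=update_attractions(self.attr.a_self, own, self.spec.alpha_opp),
            a_opp=update_attractions(self.attr.a_opp, opp, self.spec.alpha_opp),
        )


class UniformAgent:
    """Plays uniformly at random (the maximin strategy in zero-sum RPS)."""

    def __init__(self, game: GameSpec):
        self.game = game

    def reset(self) -> None:
        pass

    def policy(self) -> np.ndarray:
        n = self.game.n_actions
        return np.full(n, 1.0 / n)

    def observe(self, own: int, opp: int) -> None:
        pass


class RLAgent:
    def __init__(self, alpha: float, beta: float, game: GameSpec):
        self.alpha, self.beta = alpha, beta
        self.game = game
        self._pi = build_payoff_matrix(game).entries
        self.reset()

    def reset(self) -> None:
        self.state = bl.RLState.initial(self.game.n_actions)

    def policy(self) -> np.ndarray:
        return bl.rl_policy(self.state, self.beta)

    def observe(self, own: int, opp: int) -> None:
        self.state = bl.rl_step(self.state, own, self._pi[own, opp], self.alpha)


class EWAAgent:
    def __init__(
        self, delta: float, phi: float, rho: float, beta: float, game: GameSpec
    ):
        self.delta, self.phi, self.rho, self.beta = delta, phi, rho, beta
        self.game = game
        self._pi = build_payoff_matrix(game).entries
        self.reset()

    def reset(self) -> None:
        self.state = bl.EWAState.initial(self.game.n_actions)

    def policy(self) -> np.ndarray:
        return bl.ewa_policy(self.state, self.beta)

    def observe(self, own: int, opp: int) -> None:
        self.state = bl.ewa_step(
            self.state, own, opp, self._pi, self.delta, self.phi, self.rho
        )


class STEWAAgent:
    def __init__(self, beta: float, game: GameSpec, window: int = 1):
        self.beta = beta
        self.window = window
        self.game = game
        self._pi = build_payoff_matrix(game).entries
        self.reset()

    def reset(self) -> None:
        self.state = bl.EWAState.initial(self.game.n_actions)
        self._opp_history: list[int] = []

    def policy(self) -> np.ndarray:
        return bl.ewa_policy(self.state, self.beta)

    def observe(self, own: int, opp: int) -> None:
        self._opp_history.append(opp)
        self.state, _ = bl.stewa_step(
            self.state, own, opp, self._pi,
            np.array(self._opp_history), self.window,
        )


class ToMkAgent:
    def __init__(self, alpha: float, beta: float, k: int, game: GameSpec):
        self.alpha, self.beta, self.k = alpha, beta, int(k)
        self.game = game
        self._pi = build_payoff_matrix(game).entries
        self.reset()

    def reset(self) -> None:
        self.state = bl.ToMkState.initial(self.game.n_actions, self.k)

    def policy(self) -> np.ndarray:
        pol, self._last_preds = bl.tomk_policy(self.state, self.k, self._pi, self.beta)
        return pol

    def observe(self, own: int, opp: int) -> None:
        _, preds = bl.tomk_policy(self.state, self.k, self._pi, self.beta)
        self.state = bl.tomk_step(self.state, preds, own, opp, self.alpha)


def make_agent(model: str, params: dict, game: GameSpec):
    """Instantiate a generative agent for a registered model."""
    if model == "chase":
        return ChaseAgent(ChaseParams(**params), game)
    if model == "fp":
        return ChaseAgent(
            ChaseParams(
                alpha=params["alpha"], beta=params["beta"],
                gamma=1.0, lam=1.0, kappa=1,
            ),
            game,
        )
    if model == "rl":
        return RLAgent(params["alpha"], params["beta"], game)
    if model == "ewa":
        return EWAAgent(
            params["delta"], params["phi"], params["rho"], params["beta"], game
        )
    if model == "stewa":
        return STEWAAgent(params["beta"], game)
    if model == "tomk":
        return ToMkAgent(params["alpha"], params["beta"], params["k"], game)
    if model == "uniform":
        return UniformAgent(game)
    raise KeyError(f"unknown model {model!r}")
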