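"""Competitor learning models: RL, fictitious play, EWA, self-tuning EWA, ToMk.

Each model is exposed in two forms: readable per-trial step/policy functions
(used by the simulation agents and mirrored one-to-one in the jitted session
kernels) and a whole-session log-likelihood built on :mod:`chasegame._kernels`.
A registry maps model names to parameter specifications, likelihoods and
samplers; the fitting and validation layers work exclusively through it.

Initial conditions follow a common convention: zero for experience
equivalents, uniform for action frequencies, and the expected reward of play
against a uniformly random opponent for value estimates (zero in the
zero-sum game).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import _kernels
from .chase import ChaseParams, chase_session_loglik, softmax
from .game import GameSpec, build_payoff_matrix
from .sessions import SessionLog

__all__ = [
    "RLState",
    "EWAState",
    "ToMkState",
    "rl_step",
    "rl_policy",
    "ewa_step",
    "ewa_policy",
    "stewa_step",
    "tomk_policy",
    "tomk_step",
    "ModelSpec",
    "MODELS",
    "get_model",
    "model_loglik",
]

TOMK_OPPONENT_CONFIDENCE = 0.8  # fixed; avoids infinitely nested recursion
TOMK_INITIAL_CONFIDENCE = 0.5
STEWA_DEFAULT_WINDOW = 1


# ---------------------------------------------------------------- RL

@dataclass
class RLState:
    """Action values learned from realized payoffs (Q values)."""

    q: np.ndarray

    @classmethod
    def initial(cls, n_actions: int) -> "RLState":
        # expected reward against a uniformly random opponent: 0 in zero-sum
        return cls(q=np.zeros(n_actions))


def rl_step(
    state: RLState,
    own_action: int,
    payoff: float,
    alpha: float,
    decay_unchosen: bool = True,
) -> RLState:
    """Delta rule on realized payoff.

    The literal vector form updates every entry toward ``payoff * I(chosen)``
    so unchosen values decay toward zero; ``decay_unchosen=False`` restricts
    the update to the chosen entry.
    """
    q = state.q.copy()
    if decay_unchosen:
        target = np.zeros_like(q)
        target[own_action] = payoff
        q += alpha * (target - q)
    else:
        q[own_action] += alpha * (payoff - q[own_action])
    return RLState(q=q)


def rl_policy(state: RLState, beta: float) -> np.ndarray:
    return softmax(state.q, beta)


# ---------------------------------------------------------------- EWA

@dataclass
class EWAState:
    """Experience-weighted attractions and the experience equivalent."""

    a: np.ndarray
    n: float = 0.0

    @classmethod
    def initial(cls, n_actions: int) -> "EWAState":
        return cls(a=np.zeros(n_actions), n=0.0)


def ewa_step(
    state: EWAState,
    own_action: int,
    opp_action: int,
    pi: np.ndarray,
    delta: float,
    phi: float,
    rho: float,
) -> EWAState:
    """EWA update with foregone payoffs.

    n' = rho * n + 1;  a' = (phi * n * a + [delta + (1-delta) I(own)] * pi_cf) / n'
    where ``pi_cf`` is the counterfactual payoff vector (each own action
    against the observed opponent action).  The denominator is the updated
    experience n'.
    """
    foregone = pi[:, opp_action]
    bracket = np.full_like(state.a, delta)
    bracket[own_action] = 1.0
    n_new = rho * state.n + 1.0
    a_new = (phi * state.n * state.a + bracket * foregone) / n_new
    return EWAState(a=a_new, n=n_new)


def ewa_policy(state: EWAState, beta: float) -> np.ndarray:
    return softmax(state.a, beta)


def stewa_step(
    state: EWAState,
    own_action: int,
    opp_action: int,
    pi: np.ndarray,
    opp_history: np.ndarray,
    window: int = STEWA_DEFAULT_WINDOW,
) -> tuple[EWAState, float]:
    """Self-tuning EWA update; returns the new state and phi(t).

    The change detector phi(t) = 1 - 0.5 * sum_j (h_j - r_j)^2 compares
    cumulative (h) against recent-window (r) opponent action frequencies,
    both including the current trial; the attention function delta_j(t) is 1
    iff the foregone payoff of action j weakly exceeds the realized payoff.
    phi(t) also plays the role of rho in the experience update.
    """
    opp_history = np.asarray(opp_history, dtype=int)
    n_actions = pi.shape[0]
    t = len(opp_history)
    if t == 0 or opp_history[-1] != opp_action:
        raise ValueError("opp_history must end with the current opponent action")
    h = np.bincount(opp_history, minlength=n_actions) / t
    recent = opp_history[-min(window, t):]
    r = np.bincount(recent, minlength=n_actions) / len(recent)
    phi_t = 1.0 - 0.5 * float(np.sum((h - r) ** 2))
    foregone = pi[:, opp_action]
    realized = pi[own_action, opp_action]
    delta_vec = (foregone >= realized).astype(float)
    n_new = phi_t * state.n + 1.0
    a_new = (phi_t * state.n * state.a + delta_vec * foregone) / n_new
    return EWAState(a=a_new, n=n_new), phi_t


# ---------------------------------------------------------------- ToMk

@dataclass
class ToMkState:
    """Recency-weighted frequencies and per-level confidences.

    ``attr_opp`` tracks opponent action frequencies (the level-0 substrate),
    ``attr_self`` the agent's own action frequencies (needed to simulate the
    opponent's model of the agent).  ``c`` holds the learned confidence for
    each of the agent's reasoning levels 1..k; simulated opponent-side
    confidences are fixed at 0.8.
    """

    attr_self: np.ndarray
    attr_opp: np.ndarray
    c: np.ndarray

    @classmethod
    def initial(cls, n_actions: int, k: int) -> "ToMkState":
        return cls(
            attr_self=np.full(n_actions, 1.0 / n_actions),
            attr_opp=np.full(n_actions, 1.0 / n_actions),
            c=np.full(k, TOMK_INITIAL_CONFIDENCE),
        )


def tomk_policy(
    state: ToMkState, k: int, pi: np.ndarray, beta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Policy and per-level opponent predictions for a ToMk agent.

    The level-0 expected value responds to opponent action frequencies; each
    higher level mixes the best response to the (argmax, tie-split)
    prediction of the opponent's next-lower-level play with the lower-level
    expected value, weighted by the level's confidence.
    """
    pol, preds = _kernels.tomk_trial(
        np.asarray(state.attr_self, dtype=float),
        np.asarray(state.attr_opp, dtype=float),
        np.asarray(state.c, dtype=float),
        k,
        np.asarray(pi, dtype=float),
        float(beta),
        TOMK_OPPONENT_CONFIDENCE,
    )
    return pol, preds


def tomk_step(
    state: ToMkState,
    preds: np.ndarray,
    own_action: int,
    opp_action: int,
    alpha: float,
) -> ToMkState:
    """Confidence and frequency updates after feedback.

    Credit assignment is lowest-level: the lowest level whose prediction
    covers the observed action is reinforced; higher levels predicting the
    same action stay constant; all others decay.
    """
    c = _kernels.tomk_update_conf(
        state.c.copy(), np.asarray(preds, dtype=float), opp_action, alpha
    )
    ind_s = np.zeros_like(state.attr_self)
    ind_s[own_action] = 1.0
    ind_o = np.zeros_like(state.attr_opp)
    ind_o[opp_action] = 1.0
    return ToMkState(
        attr_self=state.attr_self + alpha * (ind_s - state.attr_self),
        attr_opp=state.attr_opp + alpha * (ind_o - state.attr_opp),
        c=c,
    )


# ---------------------------------------------------------------- registry

def _game_pi(game: GameSpec) -> np.ndarray:
    return build_payoff_matrix(game).entries


def _chase_loglik(session: SessionLog, params: dict) -> float:
    return chase_session_loglik(
        session,
        ChaseParams(
            alpha=params["alpha"],
            beta=params["beta"],
            gamma=params["gamma"],
            lam=params["lam"],
            kappa=int(params["kappa"]),
        ),
    )


def _fp_loglik(session: SessionLog, params: dict) -> float:
    # fictitious play is CHASE restricted to kappa = 1 (gamma, lambda inert)
    return chase_session_loglik(
        session,
        ChaseParams(
            alpha=params["alpha"], beta=params["beta"], gamma=1.0, lam=1.0, kappa=1
        ),
    )


def _rl_loglik(session: SessionLog, params: dict) -> float:
    acts_s, acts_o, blocks = session.to_arrays()
    ll, _ = _kernels.rl_session(
        acts_s, acts_o, blocks, _game_pi(session.game),
        params["alpha"], params["beta"], True,
    )
    return float(ll)


def _ewa_loglik(session: SessionLog, params: dict) -> float:
    acts_s, acts_o, blocks = session.to_arrays()
    ll, _ = _kernels.ewa_session(
        acts_s, acts_o, blocks, _game_pi(session.game),
        params["delta"], params["phi"], params["rho"], params["beta"],
    )
    return float(ll)


def _stewa_loglik(session: SessionLog, params: dict) -> float:
    acts_s, acts_o, blocks = session.to_arrays()
    ll, _ = _kernels.stewa_session(
        acts_s, acts_o, blocks, _game_pi(session.game),
        params["beta"], STEWA_DEFAULT_WINDOW,
    )
    return float(ll)


def _tomk_loglik(session: SessionLog, params: dict) -> float:
    acts_s, acts_o, blocks = session.to_arrays()
    ll, _ = _kernels.tomk_session(
        acts_s, acts_o, blocks, _game_pi(session.game),
        params["alpha"], params["beta"], int(params["k"]),
        TOMK_OPPONENT_CONFIDENCE, TOMK_INITIAL_CONFIDENCE,
    )
    return float(ll)


@dataclass(frozen=True)
class ModelSpec:
    """Registry entry: parameterization, likelihood and default sampler.

    ``continuous`` maps parameter name -> (transform, grid of start values);
    transforms are "logit" for rates in (0, 1) and "log" for positives.
    ``discrete`` maps parameter name -> exhaustively enumerated values.
    ``n_params`` is the count entering AIC (discrete parameters included).
    """

    name: str
    continuous: dict[str, tuple[str, tuple[float, ...]]]
    discrete: dict[str, tuple[int, ...]]
    n_params: int
    loglik: Callable[[SessionLog, dict], float]
    sampler: Callable[[np.random.Generator], dict] = field(repr=False, default=None)


def _chase_sampler(rng: np.random.Generator) -> dict:
    return {
        "alpha": rng.uniform(0.05, 0.6),
        "beta": rng.uniform(1.0, 10.0),
        "gamma": rng.uniform(1.0, 30.0),
        "lam": rng.uniform(0.5, 3.0),
        "kappa": int(rng.choice([1, 2, 3], p=[0.1, 0.1, 0.8])),
    }


def _two_param_sampler(rng: np.random.Generator) -> dict:
    return {"alpha": rng.uniform(0.05, 0.6), "beta": rng.uniform(1.0, 10.0)}


def _ewa_sampler(rng: np.random.Generator) -> dict:
    return {
        "delta": rng.uniform(0.1, 0.9),
        "phi": rng.uniform(0.2, 0.95),
        "rho": rng.uniform(0.1, 0.9),
        "beta": rng.uniform(1.0, 10.0),
    }


def _stewa_sampler(rng: np.random.Generator) -> dict:
    return {"beta": rng.uniform(1.0, 10.0)}


def _tomk_sampler(rng: np.random.Generator) -> dict:
    return {
        "alpha": rng.uniform(0.05, 0.6),
        "beta": rng.uniform(1.0, 10.0),
        "k": int(rng.integers(1, 4)),
    }


_ALPHA_GRID = (0.1, 0.3, 0.6)
_BETA_GRID = (0.5, 2.0, 6.0)

MODELS: dict[str, ModelSpec] = {
    "chase": ModelSpec(
        name="chase",
        continuous={
            "alpha": ("logit", _ALPHA_GRID),
            "beta": ("range:0:20", _BETA_GRID),
            "gamma": ("range:0:60", (1.0, 5.0, 20.0)),
            "lam": ("range:0:6", (0.7, 1.0, 2.0)),
        },
        discrete={"kappa": (1, 2, 3)},
        n_params=5,
        loglik=_chase_loglik,
        sampler=_chase_sampler,
    ),
    "rl": ModelSpec(
        name="rl",
        continuous={"alpha": ("logit", _ALPHA_GRID), "beta": ("range:0:20", _BETA_GRID)},
        discrete={},
        n_params=2,
        loglik=_rl_loglik,
        sampler=_two_param_sampler,
    ),
    "fp": ModelSpec(
        name="fp",
        continuous={"alpha": ("logit", _ALPHA_GRID), "beta": ("range:0:20", _BETA_GRID)},
        discrete={},
        n_params=2,
        loglik=_fp_loglik,
        sampler=_two_param_sampler,
    ),
    "ewa": ModelSpec(
        name="ewa",
        continuous={
            "delta": ("logit", (0.2, 0.5, 0.8)),
            "phi": ("logit", (0.3, 0.6, 0.9)),
            "rho": ("logit", (0.2, 0.5, 0.8)),
            "beta": ("range:0:20", _BETA_GRID),
        },
        discrete={},
        n_params=4,
        loglik=_ewa_loglik,
        sampler=_ewa_sampler,
    ),
    "stewa": ModelSpec(
        name="stewa",
        continuous={"beta": ("range:0:20", (0.2, 0.5, 2.0, 6.0, 15.0))},
        discrete={},
        n_params=1,
        loglik=_stewa_loglik,
        sampler=_stewa_sampler,
    ),
    "tomk": ModelSpec(
        name="tomk",
        continuous={"alpha": ("logit", _ALPHA_GRID), "beta": ("range:0:20", _BETA_GRID)},
        discrete={"k": (0, 1, 2, 3)},
        n_params=3,
        loglik=_tomk_loglik,
        sampler=_tomk_sampler,
    ),
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered: {sorted(MODELS)}"
        ) from None


def model_loglik(name: str, session: SessionLog, params: dict) -> float:
    return get_model(name).loglik(session, params)
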