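"""The CHASE model of adaptive mentalization in repeated matching games.

CHASE (cognitive hierarchy assessment) describes a player who

1. tracks the recent history of both players' actions with a delta rule
   ("attractions": exponentially decaying action frequencies),
2. reasons recursively about the opponent: a level-k policy starts from a
   level-0 attraction-driven policy and applies k softmax best responses to
   it (odd levels are other-referential, even levels self-referential),
3. infers the opponent's level of sophistication by Bayesian updating of a
   belief distribution over levels 0..kappa-1, using a sensitivity-distorted
   likelihood, and
4. noisily best responds to the belief-weighted prediction of the opponent's
   next action.

Five parameters govern the agent: ``alpha`` (attraction update rate),
``beta`` (inverse softmax temperature, shared across all simulated
policies), ``gamma`` (sensitivity to level evidence), ``lam`` (weight on
loss payoffs in the internal matrix) and ``kappa`` (maximum sophistication,
the number of opponent levels entertained).

Trial-wise model derivatives for downstream (e.g. model-based neuroimaging)
analyses are exposed alongside the likelihood: the choice value CV (expected
payoff of the chosen action under the integrated opponent prediction), the
action prediction error APE (one minus the predicted probability of the
observed opponent action), and the belief update BU (KL divergence from
prior to posterior level beliefs, in nats).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .game import GameSpec, PayoffMatrix, build_payoff_matrix, scale_losses
from .sessions import SessionLog

__all__ = [
    "ChaseParams",
    "AttractionPair",
    "BeliefState",
    "ChaseState",
    "TrialDerivatives",
    "softmax",
    "update_attractions",
    "level_policy",
    "level_likelihood",
    "distort_likelihood",
    "bayes_update",
    "belief_update_kl",
    "integrated_policy",
    "choice_value",
    "action_prediction_error",
    "init_chase_state",
    "chase_step",
    "chase_session_loglik",
    "chase_session_derivatives",
]


@dataclass(frozen=True)
class ChaseParams:
    """The five CHASE parameters (natural scale)."""

    alpha: float = 0.3
    beta: float = 5.0
    gamma: float = 10.0
    lam: float = 1.0
    kappa: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")
        if self.kappa < 1:
            raise ValueError(f"kappa must be >= 1, got {self.kappa}")


@dataclass
class AttractionPair:
    """Attraction vectors for own (`a_self`) and opponent (`a_opp`) actions."""

    a_self: np.ndarray
    a_opp: np.ndarray

    @classmethod
    def uniform(cls, n_actions: int) -> "AttractionPair":
        return cls(
            a_self=np.full(n_actions, 1.0 / n_actions),
            a_opp=np.full(n_actions, 1.0 / n_actions),
        )


@dataclass
class BeliefState:
    """Belief over opponent levels 0..kappa-1 plus last-trial evidence."""

    b: np.ndarray
    last_likelihood: np.ndarray | None = None
    last_distorted: np.ndarray | None = None
    last_bu: float = 0.0

    @classmethod
    def uniform(cls, kappa: int) -> "BeliefState":
        return cls(b=np.full(kappa, 1.0 / kappa))


@dataclass
class ChaseState:
    attractions: AttractionPair
    beliefs: BeliefState


@dataclass
class TrialDerivatives:
    """Model-derived quantities for a single trial."""

    cv: float
    ape: float
    bu: float
    predicted_opp: np.ndarray
    own_policy: np.ndarray
    modal_level_response: int


def softmax(x: np.ndarray, temp: float) -> np.ndarray:
    """Softmax with inverse temperature ``temp``; temp == 0 gives uniform."""
    if temp < 0:
        raise ValueError(f"inverse temperature must be >= 0, got {temp}")
    x = np.asarray(x, dtype=float)
    if temp == 0.0:
        return np.full(x.shape, 1.0 / x.size)
    z = temp * x
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def update_attractions(a: np.ndarray, chosen: int, alpha: float) -> np.ndarray:
    """Delta rule toward the indicator of the chosen action; sum-preserving."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    ind = np.zeros_like(a)
    ind[chosen] = 1.0
    return a + alpha * (ind - a)


def level_policy(
    k: int,
    attr: AttractionPair,
    perspective: str,
    pi_scaled: PayoffMatrix | np.ndarray,
    beta: float,
) -> np.ndarray:
    """Level-k policy from the stated perspective.

    ``perspective`` is ``"self_play"`` (the agent's own level-k behavior) or
    ``"opponent_prediction"`` (what a level-k opponent would play).  The
    level-0 base follows the parity rule: even levels ground in the target
    player's own action history, odd levels in the other player's.
    """
    if k < 0:
        raise ValueError(f"level must be >= 0, got {k}")
    if perspective not in ("self_play", "opponent_prediction"):
        raise ValueError(f"unknown perspective {perspective!r}")
    pi = pi_scaled.entries if isinstance(pi_scaled, PayoffMatrix) else pi_scaled
    return _kernels.level_pred(
        k,
        np.asarray(attr.a_self, dtype=float),
        np.asarray(attr.a_opp, dtype=float),
        np.asarray(pi, dtype=float),
        float(beta),
        perspective == "self_play",
    )


def level_likelihood(
    a_opp_observed: int,
    attr: AttractionPair,
    kappa: int,
    pi_scaled: PayoffMatrix | np.ndarray,
    beta: float,
) -> np.ndarray:
    """Likelihood of the observed opponent action under each level 0..kappa-1."""
    if kappa < 1:
        raise ValueError(f"kappa must be >= 1, got {kappa}")
    return np.array(
        [
            level_policy(k, attr, "opponent_prediction", pi_scaled, beta)[
                a_opp_observed
            ]
            for k in range(kappa)
        ]
    )


def distort_likelihood(lik: np.ndarray, gamma: float) -> np.ndarray:
    """Softmax-distort the level likelihood with sensitivity ``gamma``.

    gamma == 0 yields a uniform (evidence-insensitive) learner; large gamma
    sharpens the evidence toward the most likely level.
    """
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    return softmax(np.asarray(lik, dtype=float), gamma)


def bayes_update(b: np.ndarray, l_hat: np.ndarray) -> np.ndarray:
    """Posterior over levels: elementwise product with the prior, renormalized."""
    post = np.asarray(l_hat, dtype=float) * np.asarray(b, dtype=float)
    z = post.sum()
    if z <= 0:
        raise ValueError("degenerate belief update: all posterior mass is zero")
    return post / z


def belief_update_kl(b_post: np.ndarray, b_prior: np.ndarray) -> float:
    """KL divergence (nats) from prior to posterior beliefs, 0*log0 = 0."""
    b_post = np.asarray(b_post, dtype=float)
    b_prior = np.asarray(b_prior, dtype=float)
    if np.any((b_prior <= 0) & (b_post > 0)):
        raise ValueError("infinite divergence: posterior mass on zero-prior level")
    mask = b_post > 0
    kl = float(np.sum(b_post[mask] * np.log(b_post[mask] / b_prior[mask])))
    return max(kl, 0.0)  # KL >= 0 exactly; clip floating-point rounding


def integrated_policy(
    b: np.ndarray,
    per_level_opp_predictions: np.ndarray,
    pi_scaled: PayoffMatrix | np.ndarray,
    beta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Belief-weighted opponent prediction and the noisy best response to it."""
    pi = pi_scaled.entries if isinstance(pi_scaled, PayoffMatrix) else pi_scaled
    predicted_opp = np.asarray(b, dtype=float) @ np.asarray(
        per_level_opp_predictions, dtype=float
    )
    own_policy = softmax(np.asarray(pi, dtype=float) @ predicted_opp, beta)
    return own_policy, predicted_opp


def choice_value(
    own_action: int,
    predicted_opp: np.ndarray,
    pi_scaled: PayoffMatrix | np.ndarray,
) -> float:
    """Expected (loss-weighted) payoff of the chosen action."""
    pi = pi_scaled.entries if isinstance(pi_scaled, PayoffMatrix) else pi_scaled
    return float((np.asarray(pi, dtype=float) @ np.asarray(predicted_opp))[own_action])


def action_prediction_error(observed_opp: int, predicted_opp: np.ndarray) -> float:
    """1 minus the predicted probability of the observed opponent action."""
    return float(1.0 - np.asarray(predicted_opp)[observed_opp])


def init_chase_state(n_actions: int, kappa: int) -> ChaseState:
    """Fresh block-start state: uniform attractions and level beliefs."""
    return ChaseState(
        attractions=AttractionPair.uniform(n_actions),
        beliefs=BeliefState.uniform(kappa),
    )


def scaled_matrix(game: GameSpec, lam: float) -> np.ndarray:
    """The agent-internal, loss-weighted payoff matrix for a game."""
    return scale_losses(build_payoff_matrix(game), lam).entries


def chase_step(
    state: ChaseState,
    own_action: int,
    opp_action: int,
    params: ChaseParams,
    pi_scaled: PayoffMatrix | np.ndarray,
) -> tuple[ChaseState, TrialDerivatives]:
    """Advance the CHASE state by one observed trial.

    Computation order: (i) per-level opponent predictions and the integrated
    policy from the pre-trial state (choice value refers to the chosen
    action); (ii) on feedback, the action prediction error, then the level
    likelihood from pre-trial attractions, its distortion, and the Bayesian
    belief update (BU is the KL divergence of the update); (iii) attraction
    updates from both observed actions.
    """
    pi = pi_scaled.entries if isinstance(pi_scaled, PayoffMatrix) else pi_scaled
    attr, bel = state.attractions, state.beliefs
    kappa = params.kappa

    preds = np.stack(
        [
            level_policy(k, attr, "opponent_prediction", pi, params.beta)
            for k in range(kappa)
        ]
    )
    own_policy, predicted_opp = integrated_policy(bel.b, preds, pi, params.beta)
    cv = choice_value(own_action, predicted_opp, pi)
    modal = int(np.argmax(bel.b)) + 1  # argmax ties break toward lower level

    ape = action_prediction_error(opp_action, predicted_opp)
    lik = preds[:, opp_action]
    l_hat = distort_likelihood(lik, params.gamma)
    b_post = bayes_update(bel.b, l_hat)
    bu = belief_update_kl(b_post, bel.b)

    new_state = ChaseState(
        attractions=AttractionPair(
            a_self=update_attractions(attr.a_self, own_action, params.alpha),
            a_opp=update_attractions(attr.a_opp, opp_action, params.alpha),
        ),
        beliefs=BeliefState(
            b=b_post, last_likelihood=lik, last_distorted=l_hat, last_bu=bu
        ),
    )
    deriv = TrialDerivatives(
        cv=cv,
        ape=ape,
        bu=bu,
        predicted_opp=predicted_opp,
        own_policy=own_policy,
        modal_level_response=modal,
    )
    return new_state, deriv


def _session_kernel_args(session: SessionLog, params: ChaseParams):
    acts_s, acts_o, blocks = session.to_arrays()
    pi = scaled_matrix(session.game, params.lam)
    return acts_s, acts_o, blocks, pi


def chase_session_loglik(session: SessionLog, params: ChaseParams) -> float:
    """Summed log choice probability across all trials, block-wise reset.

    One parameter set covers all blocks; per-trial probabilities are floored
    at 1e-12 before the log.
    """
    acts_s, acts_o, blocks, pi = _session_kernel_args(session, params)
    ll = _kernels.chase_loglik(
        acts_s, acts_o, blocks, pi,
        params.alpha, params.beta, params.gamma, params.kappa,
    )
    if not np.isfinite(ll):
        raise FloatingPointError(f"non-finite log-likelihood for params {params}")
    return float(ll)


def chase_session_derivatives(
    session: SessionLog, params: ChaseParams
) -> pd.DataFrame:
    """Tidy per-trial model derivatives for a fitted participant.

    Columns: participant, block, trial (within block), cv, ape, bu, bu_z
    (z-scored within participant at this export layer; constant BU maps to
    zero), modal_level_response.
    """
    acts_s, acts_o, blocks, pi = _session_kernel_args(session, params)
    _, own_pols, pred_opps, b_prior, b_post, cv, ape, bu = _kernels.chase_session(
        acts_s, acts_o, blocks, pi,
        params.alpha, params.beta, params.gamma, params.kappa,
    )
    modal = b_prior.argmax(axis=1) + 1
    trial_in_block = np.concatenate(
        [np.arange(b.n_trials) for b in session.blocks]
    )
    sd = bu.std()
    bu_z = (bu - bu.mean()) / sd if sd > 0 else np.zeros_like(bu)
    return pd.DataFrame(
        {
            "participant": session.participant,
            "block": blocks,
            "trial": trial_in_block,
            "cv": cv,
            "ape": ape,
            "bu": bu,
            "bu_z": bu_z,
            "modal_level_response": modal,
        }
    )
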