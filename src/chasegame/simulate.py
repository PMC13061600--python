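"""Synthetic experiments: blocks of play against fixed-level opponents.

The default design mirrors the in-scanner protocol the models were built
for: six blocks of 40 trials, opponent sophistication levels 0, 1 and 2
each encountered twice, in a per-participant counterbalanced order without
immediate repeats.  All state (both players') resets at block start, and
every run is replayable from its seed.
"""

from __future__ import annotations

import numpy as np

from .agents import FixedLevelOpponent, OpponentSpec, make_agent
from .baselines import get_model
from .game import GameSpec, build_payoff_matrix
from .sessions import BlockRecord, SessionLog

__all__ = [
    "OpponentSpec",
    "play_block",
    "play_session",
    "counterbalanced_levels",
    "generate_dataset",
]

DEFAULT_TRIALS_PER_BLOCK = 40
DEFAULT_LEVELS = (0, 1, 2)
DEFAULT_REPEATS = 2  # each level twice -> six blocks


def play_block(
    agent,
    opponent,
    n_trials: int,
    rng: np.random.Generator,
    game: GameSpec,
    opponent_meta: dict | None = None,
) -> BlockRecord:
    """Simulate one block: both sides freshly reset, simultaneous sampling.

    Each trial, both policies are computed from the pre-trial states, both
    actions sampled, then both agents observe both actions.
    """
    pi = build_payoff_matrix(game).entries
    agent.reset()
    opponent.reset()
    n = game.n_actions
    a_s = np.empty(n_trials, dtype=np.int64)
    a_o = np.empty(n_trials, dtype=np.int64)
    pay_s = np.empty(n_trials)
    pay_o = np.empty(n_trials)
    for t in range(n_trials):
        p_agent = agent.policy()
        p_opp = opponent.policy()
        a_s[t] = rng.choice(n, p=p_agent)
        a_o[t] = rng.choice(n, p=p_opp)
        pay_s[t] = pi[a_s[t], a_o[t]]
        pay_o[t] = pi[a_o[t], a_s[t]]
        agent.observe(a_s[t], a_o[t])
        opponent.observe(a_o[t], a_s[t])  # from the opponent's perspective
    return BlockRecord(
        actions_self=a_s,
        actions_opp=a_o,
        payoffs_self=pay_s,
        payoffs_opp=pay_o,
        opponent=opponent_meta or {},
    )


def counterbalanced_levels(
    rng: np.random.Generator,
    levels: tuple[int, ...] = DEFAULT_LEVELS,
    repeats: int = DEFAULT_REPEATS,
) -> list[int]:
    """Random block order with each level ``repeats`` times, no immediate repeats.

    Sequential sampling weighted by remaining counts; a level holding more
    than half of the remaining slots is forced to keep the order feasible.
    """
    if len(set(levels)) == 1:  # single opponent type: repeats are unavoidable
        return [int(levels[0])] * repeats
    counts = {int(l): repeats for l in levels}
    order: list[int] = []
    prev = None
    total = len(levels) * repeats
    for pos in range(total):
        remaining = total - pos
        allowed = [l for l, c in counts.items() if c > 0 and l != prev]
        if not allowed:
            raise RuntimeError("could not build a repeat-free block order")
        forced = [l for l in allowed if counts[l] >= (remaining + 1) // 2]
        if forced:
            choice = int(forced[0] if len(forced) == 1 else rng.choice(forced))
        else:
            weights = np.array([counts[l] for l in allowed], dtype=float)
            choice = int(rng.choice(allowed, p=weights / weights.sum()))
        order.append(choice)
        counts[choice] -= 1
        prev = choice
    return order


def play_session(
    agent,
    participant: str,
    rng: np.random.Generator,
    game: GameSpec | None = None,
    trials_per_block: int = DEFAULT_TRIALS_PER_BLOCK,
    levels: tuple[int, ...] = DEFAULT_LEVELS,
    repeats: int = DEFAULT_REPEATS,
    opponent_kwargs: dict | None = None,
    seed: int | None = None,
) -> SessionLog:
    """One participant's full session against counterbalanced fixed-level opponents."""
    game = game or GameSpec()
    opponent_kwargs = opponent_kwargs or {}
    order = counterbalanced_levels(rng, levels, repeats)
    blocks = []
    for level in order:
        spec = OpponentSpec(level=level, **opponent_kwargs)
        opp = FixedLevelOpponent(spec, game)
        blocks.append(
            play_block(agent, opp, trials_per_block, rng, game, spec.to_dict())
        )
    return SessionLog(participant=participant, game=game, blocks=blocks, seed=seed)


def generate_dataset(
    n_participants: int,
    model: str = "chase",
    seed: int = 0,
    game: GameSpec | None = None,
    trials_per_block: int = DEFAULT_TRIALS_PER_BLOCK,
    levels: tuple[int, ...] = DEFAULT_LEVELS,
    repeats: int = DEFAULT_REPEATS,
    opponent_kwargs: dict | None = None,
    sampler=None,
    params: dict | None = None,
) -> tuple[list[SessionLog], list[dict]]:
    """Simulate a cohort playing the default six-block design.

    Per-participant parameters come from ``params`` (shared point values),
    a custom ``sampler(rng) -> dict``, or the model's registered default
    sampler.  Per-participant RNGs are spawned deterministically from the
    master seed.  Returns (sessions, generating parameter dicts).
    """
    if n_participants < 0:
        raise ValueError("n_participants must be >= 0")
    game = game or GameSpec()
    spec = get_model(model) if model != "uniform" else None
    if sampler is None and params is None and spec is not None:
        sampler = spec.sampler
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants)
    sessions: list[SessionLog] = []
    gen_params: list[dict] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        p = dict(params) if params is not None else (sampler(rng) if sampler else {})
        agent = make_agent(model, p, game)
        sessions.append(
            play_session(
                agent,
                participant=f"sim{i:03d}",
                rng=rng,
                game=game,
                trials_per_block=trials_per_block,
                levels=levels,
                repeats=repeats,
                opponent_kwargs=opponent_kwargs,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
        )
        gen_params.append(p)
    return sessions, gen_params
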