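import numpy as np
import pytest

from chasegame import GameSpec
from chasegame.sessions import BlockRecord, SessionLog


@pytest.fixture(scope="session")
def game():
    return GameSpec()


def make_random_session(
    rng, n_blocks=2, n_trials=20, n_actions=3, participant="rnd"
):
    """Uniformly random play, payoffs consistent with the zero-sum game."""
    from chasegame import build_payoff_matrix

    game = GameSpec(n_actions=n_actions)
    pi = build_payoff_matrix(game).entries
    blocks = []
    for _ in range(n_blocks):
        a_s = rng.integers(0, n_actions, n_trials)
        a_o = rng.integers(0, n_actions, n_trials)
        blocks.append(
            BlockRecord(
                actions_self=a_s,
                actions_opp=a_o,
                payoffs_self=pi[a_s, a_o],
                payoffs_opp=pi[a_o, a_s],
                opponent={"level": 0},
            )
        )
    return SessionLog(participant=participant, game=game, blocks=blocks)


@pytest.fixture
def random_session():
    return make_random_session(np.random.default_rng(0))
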