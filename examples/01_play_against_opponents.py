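"""Simulate an adaptive CHASE player against fixed-level opponents.

An agent with maximum sophistication kappa=3 plays one 40-trial block
against each opponent level (0, 1, 2).  The printed mean payoff per round
should be clearly positive for every level: the agent infers the opponent's
sophistication from its actions and settles on the one-step-higher
best-response strategy.
"""

import numpy as np

from chasegame import (
    ChaseAgent,
    ChaseParams,
    FixedLevelOpponent,
    GameSpec,
    OpponentSpec,
    play_block,
)

game = GameSpec()
params = ChaseParams(alpha=0.3, beta=8.0, gamma=10.0, lam=1.0, kappa=3)
rng = np.random.default_rng(0)

for level in (0, 1, 2):
    agent = ChaseAgent(params, game)
    opponent = FixedLevelOpponent(OpponentSpec(level=level), game)
    block = play_block(agent, opponent, n_trials=40, rng=rng, game=game)
    final_belief = agent.state.beliefs.b
    print(
        f"opponent level {level}: mean payoff {block.payoffs_self.mean():+.3f}, "
        f"final belief over levels {np.round(final_belief, 2)}"
    )

print(
    "\nThe belief vector spans opponent levels 0..2; after 40 trials most "
    "mass should sit on the true opponent level."
)
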