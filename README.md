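# chasegame

Computational modeling of **adaptive mentalization** in repeated
rock–paper–scissors-style games: how a player infers *how deeply an opponent
reasons* and adapts their own strategy in response.

The package is built for researchers in computational cognitive science and
decision neuroscience who want to simulate, fit and validate opponent models
on repeated-game data. Its core is the **CHASE** (cognitive hierarchy
assessment) model, together with five competitor learning models, a
maximum-likelihood fitting pipeline, random-effects Bayesian model
selection, and the validation battery (parameter/model recovery, posterior
predictive checks, trial-wise strategy labeling) needed to trust the fits.

## The model

Play happens on an action circle: with actions `1..n`, picking the number
one step ahead of the opponent's number wins (±1 payoff, ties 0). CHASE
assumes:

- **Attraction learning.** Nonstrategic (level-0) play follows recency-
  weighted action frequencies, updated by a delta rule
  `A ← A + α (I(a) − A)` and read out through a softmax with inverse
  temperature β.
- **Recursive reasoning.** A level-k policy applies k softmax best responses
  `p ← σ(Π p | β)` to a level-0 base, where Π is the payoff matrix; odd
  levels ground in the *other* player's action history and even levels in
  one's *own* (a level-1 player best-responds to your frequencies; a level-2
  player best-responds to the response to *their* frequencies).
- **Level inference.** An adaptive player with maximum sophistication κ
  holds a belief distribution B(k) over opponent levels 0..κ−1, updated by
  Bayes' rule from the likelihood of each observed opponent action under
  each level — distorted by a sensitivity parameter γ (`L̂ = σ(L | γ)`) — and
  noisily best-responds to the belief-weighted opponent prediction.
- **Loss weighting.** A parameter λ rescales the −1 entries of the player's
  internal payoff matrix.

The five free parameters are α (learning rate), β (choice noise),
γ (sensitivity to level evidence), λ (loss weight) and κ (maximum
sophistication). The model also yields trial-wise signals for model-based
analyses: the **choice value** CV (expected payoff of the chosen action),
the **action prediction error** APE (1 − predicted probability of the
observed opponent action) and the **belief update** BU (KL divergence
between successive level beliefs).

Competitor models: reinforcement learning (delta rule on realized payoffs),
fictitious play (= CHASE with κ = 1), experience-weighted attraction (EWA),
self-tuning EWA, and the confidence-based ToMk hierarchy.

## Worked example

```python
import numpy as np
from chasegame import (ChaseAgent, ChaseParams, FixedLevelOpponent,
                       GameSpec, OpponentSpec, play_block)

game = GameSpec()                      # 3-action zero-sum circle game
params = ChaseParams(alpha=0.3, beta=8.0, gamma=10.0, lam=1.0, kappa=3)
rng = np.random.default_rng(0)
for level in (0, 1, 2):
    agent = ChaseAgent(params, game)
    opp = FixedLevelOpponent(OpponentSpec(level=level), game)
    block = play_block(agent, opp, n_trials=40, rng=rng, game=game)
    print(level, round(block.payoffs_self.mean(), 3),
          np.round(agent.state.beliefs.b, 2))
```

prints

```
0 0.55 [1. 0. 0.]
1 0.8  [0. 1. 0.]
2 0.8  [0. 0. 1.]
```

i.e. the adaptive agent earns a clearly positive score per round against
every fixed opponent level, and its final belief over opponent levels
(right) concentrates on the true level. The scripts in `examples/` walk
through the other capabilities: fitting and model comparison
(`02_fit_and_compare.py`), parameter recovery (`03_parameter_recovery.py`),
trial-wise regressor export (`04_trial_regressors.py`) and permutation-based
strategy labeling (`05_level_assignment.py`).

A thin CLI mirrors the pipeline for shell use:

```bash
chasegame simulate --config cfg.yaml --out sims/
chasegame fit sims/ --model chase --model rl --out fits.csv
chasegame compare fits.csv --out pxp.csv
```

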