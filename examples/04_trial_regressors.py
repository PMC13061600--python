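"""Export trial-wise model-derived regressors (CV, APE, BU).

Simulates one CHASE participant, then replays the session under its
generating parameters to extract per-trial signals used in model-based
analyses: the choice value (expected payoff of the chosen action), the
action prediction error (1 minus the predicted probability of the observed
opponent action) and the belief update (KL divergence between successive
beliefs about the opponent's level, z-scored within participant).  The
belief-update signal should shrink over the course of each block as the
agent settles on the opponent's level.
"""

import pandas as pd

from chasegame import ChaseParams, chase_session_derivatives, generate_dataset
from chasegame.validate import bu_timecourse

sessions, gen = generate_dataset(1, model="chase", seed=4)
params = ChaseParams(**gen[0])
derivs = chase_session_derivatives(sessions[0], params)
print(derivs.head(10).round(3).to_string(index=False))

curve, slopes = bu_timecourse(derivs)
early = curve[curve.trial < 10]["bu_mean"].mean()
late = curve[curve.trial >= 30]["bu_mean"].mean()
print(f"\nmean BU (z) trials 0-9: {early:+.3f}; trials 30-39: {late:+.3f}")
print(f"per-participant BU slope: {slopes.iloc[0]:+.4f} (negative = settling)")
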