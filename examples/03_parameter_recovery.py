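"""Parameter recovery: simulate, refit, correlate.

Draws 16 synthetic CHASE players from the documented parameter sampler,
simulates the six-block design, refits each player by maximum likelihood
and prints generating-vs-recovered Pearson correlations.  The attraction
rate alpha and sophistication kappa recover almost perfectly; the level
sensitivity gamma is only weakly identified in this design because all
large gamma values produce near-identical (fast) belief convergence.
"""

from chasegame import parameter_recovery

report = parameter_recovery(n_participants=16, seed=0)
for name, r in report.correlations.items():
    print(f"{name:>6}: r = {r:+.3f}")
print(f"\nfailed fits: {report.n_failed}")
print(report.data[["gen_alpha", "rec_alpha", "gen_kappa", "rec_kappa"]].round(3))
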