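# Methods

This note documents the models, the estimation machinery, the synthetic
data design and the numerical choices made in `chasegame`, at the level of
detail needed to interpret (and distrust appropriately) the numbers the
package produces.

## Game

The games are circular matching games: `n ≥ 3` actions on a circle, action
`i` beats `i − 1 (mod n)`. The zero-sum payoff matrix has entries
`Π[i, j] = +1` if `i ≡ j+1 (mod n)`, `−1` if `j ≡ i+1`, `0` otherwise; a
non-zero-sum variant takes configurable (win, loss, tie) payoffs, default
(1, 0, 0), since no canonical table exists for it. Actions are 0-indexed
internally (external files may label them 1..n). An agent's *internal*
matrix may rescale losses: `Π[i,j] → −λ` wherever `Π[i,j] = −1`. The scaled
matrix is used everywhere inside that agent's reasoning — the level-k
recursion, the level likelihood, the integrated best response and the
choice value — while logged game outcomes always use the raw matrix.

## The CHASE agent

State per block: two attraction vectors (own and opponent action
frequencies, both initialized uniform) and a belief vector over opponent
levels `0..κ−1` (initialized uniform). Per trial, in order:

1. **Predict.** For each level `k < κ`, the predicted opponent policy is
   built by applying `k` softmax best responses `p ← σ(Π_λ p | β)` to a
   softmaxed level-0 base; the base is the opponent's own history for even
   `k` and the agent's history for odd `k` (mirrored when generating the
   agent's own level-k play). The integrated prediction is the
   belief-weighted mixture; the agent's policy is `σ(Π_λ · prediction | β)`.
   The choice value CV is the expected (λ-weighted) payoff of the chosen
   action under the integrated prediction.
2. **Evaluate.** On feedback, APE = 1 − predicted probability of the
   observed opponent action. The level likelihood (the probability each
   level assigns to the observed action) is softmax-distorted with
   sensitivity γ and combined with the prior belief by Bayes' rule; BU is
   the KL divergence (nats, natural log) from prior to posterior.
3. **Learn.** Both attraction vectors move toward the indicators of the two
   observed actions with shared rate α.

The same β governs the agent's own choice noise and the noise it attributes
to all simulated opponents (no separate opponent-noise parameter exists
among the five). Beliefs span κ levels (0..κ−1): adapting to a level-2
opponent with κ = 3 requires a belief slot for level 2. The per-trial
modal-level readout is `argmax` of the *pre-choice* belief plus one, ties
broken toward the lower level (the conservative assignment). BU is z-scored
within participant only at the regressor-export layer, never inside the
model; sessions with identically zero BU (γ = 0) export zeros.

## Competitor models

- **RL**: delta rule on realized payoffs, `q ← q + α (π·I(a) − q)` in the
  literal vector form — unchosen values decay toward zero. (The
  chosen-entry-only variant is available behind `decay_unchosen=False`.)
  Values start at the expected payoff against a uniformly random opponent
  (zero in the zero-sum game). Two parameters (α, β).
- **Fictitious play**: identical to CHASE with κ = 1 (γ is inert; λ fixed
  at 1). Two parameters.
- **EWA**: `n' = ρ n + 1`,
  `A ← (φ n A + [δ + (1−δ) I(own)] ⊙ π_cf) / n'`, with foregone payoff
  vector `π_cf` and the *updated* experience in the denominator (the only
  form that is finite at the zero-experience start). Four fitted parameters
  (δ, φ, ρ, β); initial attractions zero, experience zero.
- **Self-tuning EWA**: φ(t) becomes a change detector,
  `1 − ½ Σ_j (h_j − r_j)²`, comparing cumulative against recent-window
  opponent action frequencies (window default 1, configurable), and δ
  becomes an attention vector selecting actions whose foregone payoff
  weakly exceeds the realized payoff; ρ = φ(t). Only β is fitted.
- **ToMk**: level-0 responds to opponent action frequencies through the
  payoff matrix; each higher level mixes the best response to the argmax
  prediction of the opponent's next-lower level with the lower level's
  expected values, weighted by a learned per-level confidence (initialized
  at 0.5). Confidences update by a delta rule with lowest-level credit:
  the lowest level whose prediction covers the observed action is
  reinforced, higher levels predicting the same action stay constant, all
  others decay. Simulated opponent-side confidences are fixed at 0.8.
  Argmax ties split mass uniformly (first-index tie-breaking would inject
  an action-labeling artifact). Fitted: α, β plus the level k enumerated
  over 0..3; k counts as a parameter toward AIC (3 total), mirroring κ in
  CHASE.

## Synthetic data

The default design mirrors the in-scanner protocol the models target: six
blocks of 40 trials, fixed-opponent levels {0, 1, 2} each twice, in a
per-participant random order without immediate repetitions. All state (both
sides') resets at block start. Artificial opponents use the CHASE learning
rule and recursion pinned to one level — no belief updating — with noise
parameterized as an inverse temperature and a lapse rate (uniform random
action). Defaults `alpha_opp = 0.3`, `beta_opp = 6`, `lapse = 0.1` were
chosen once so that a low-noise κ = 3 agent earns clearly positive scores
against all three levels; the original calibrated noise structure of such
opponents is not public, so this lapse+temperature scheme is an explicit
stand-in, and results that depend on *how* opponents deviate from their
strategy (notably the identifiability of γ, below) will differ from
human-facing setups.

Cohort parameter sampler defaults (documented, overridable):
α ~ U(0.05, 0.6), β ~ U(1, 10), γ ~ U(1, 30), λ ~ U(0.5, 3),
κ ∈ {1, 2, 3} with probabilities (0.1, 0.1, 0.8). Per-participant RNG
streams are spawned from a single master seed; a session round-trips
losslessly through CSV + JSON sidecar.

What the generator does *not* emulate: response times, within-person
parameter drift, the calibrated opponent noise episodes mentioned above,
and human deviations from all candidate models. Passing recovery tests
therefore demonstrates internal consistency of simulation + estimation, not
that human data would identify the same parameters equally well.

## Estimation

Maximum likelihood per participant across all blocks (the model is agnostic
to opponent identity; state resets each block). Continuous parameters are
optimized on an unconstrained transformed scale — logit for rates in (0,1),
scaled logit over a plausible range for positive parameters (β in (0, 20),
γ in (0, 60), λ in (0, 6)) — by a crossed grid search (3–5 values per
parameter, capped at 200 evaluations) followed by BFGS polishing of the
best three grid points (gradient tolerance 1e−6, max 300 iterations).
Discrete parameters (κ ≤ 3 by default, ToMk's k ≤ 3) are enumerated
exhaustively. Range-bounded transforms rather than an unbounded log are
used because several likelihoods have flat shoulders (e.g. all large β are
near-equivalent once policies saturate); unbounded ML then wanders to
arbitrarily large, likelihood-equivalent magnitudes, which destroys
moment-based summaries of the estimates. Per-trial choice probabilities are
floored at 1e−12 before the log. AIC = 2p − 2·logL with discrete parameters
counted (CHASE p = 5, RL/FP p = 2, EWA p = 4, stEWA p = 1, ToMk p = 3).

Group-level comparison uses random-effects Bayesian model selection:
a variational Dirichlet scheme over per-participant log evidence
(approximated as −AIC/2), uniform prior counts, convergence when the change
in the Dirichlet parameter falls below 1e−8 (max 500 iterations).
Exceedance probabilities come from 100,000 Dirichlet draws with a fixed
seed (Monte-Carlo s.e. < 0.005); the Bayesian omnibus risk compares the
variational free energy against the equal-frequency null,
`BOR = 1/(1 + exp(F1 − F0))`, and the protected exceedance probability is
`PXP = EP·(1 − BOR) + BOR/M`.

## Validation battery

- **Parameter recovery**: simulate a cohort from the sampler, refit,
  Pearson-correlate generating with recovered values (κ entered as its
  integer value). Undefined correlations under a degenerate sampler are
  reported as NaN, not errors.
- **Model recovery**: every registered model generates; every model fits;
  the confusion matrix tabulates best-AIC winners per simulation.
- **Posterior predictive check**: per opponent level and within-block trial
  position, the frequency with which actions match the *stylized* correct-
  level best response — the level-(L+1) policy computed on the running
  history with argmax steps (no noise), λ = 1 and a reference attraction
  rate (default 0.3) — minus chance 1/n. Argmax ties split credit uniformly
  so uniform play scores exactly at chance in expectation.
- **Trial-level strategy labels**: per candidate level, a trailing
  10-trial-window mean of stylized-match credits; the null shuffles the
  participant's own actions across the session (opponent actions and block
  boundaries intact) and uses the 95th percentile of the *maximum over
  levels* as a single threshold, controlling the overall false-assignment
  rate. A within-block shuffle cannot work here: successful level play is
  locally near-constant and thus invariant under it. Because window scores
  are discrete and autocorrelated, realized false-assignment rates sit at
  or below the nominal 5% (conservative). The whole scheme is a
  reconstruction; window, percentile and statistic are configurable.
- **BU time course**: trial-indexed mean/s.d. of within-participant
  z-scored BU plus per-participant least-squares slopes on the
  within-block trial index.

## Problem sizes

The shipped test suite and `scripts/acceptance.py` run parameter recovery
with 48 synthetic participants × 240 trials, model recovery with 12–20
simulations per generating model (all six models fit to each), BMS sanity
checks with 20 synthetic participants, and behavioral-signature cohorts of
12; these sizes give stable qualitative results while keeping a full run in
the minutes range on one CPU.

## Known limitations

- **γ is weakly identified in the six-block design.** The distorted level
  likelihood saturates: for γ above roughly 8, beliefs converge to the true
  opponent level within one or two trials, so all large γ values are
  behaviorally equivalent and γ information accrues only during the ~6
  block-start transitions. Generating γ uniformly on (1, 30) therefore
  yields low generating-vs-recovered correlations no matter how much
  per-block data is added (verified: γ-only ML with every other parameter
  held at its true value remains noisy, while the pooled-likelihood profile
  does peak at the generating value, i.e. the estimator is consistent).
  In the shipped 48-participant recovery runs, α and κ recover nearly
  perfectly (r ≈ 0.94–1.0), β at r ≈ 0.7–0.8 and λ at r ≈ 0.4–0.8
  (seed-dependent; both are limited by the same flat-shoulder effect at
  large magnitudes), while γ sits around r ≈ 0.1–0.3. Designs with many
  short blocks, or opponents whose strategy shifts within blocks, would
  identify γ better.
- Variational BMS with −AIC/2 evidence inherits AIC's complexity
  approximation; with few participants PXP is intentionally conservative
  (BOR shrinks it toward 1/M).
- The stylized best response used for PPC and strategy labels fixes the
  attraction rate (default 0.3) rather than marginalizing over it; labels
  near block starts are intrinsically unreliable while histories are flat.
- ToMk's self-tuning constants (initial confidence 0.5, opponent confidence
  0.8, stEWA window 1) follow the cited conventions but are configurable;
  ToMk ties under flat histories make its early-trial behavior sensitive to
  the uniform tie-split convention.
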