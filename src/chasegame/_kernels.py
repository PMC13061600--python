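"""Numba-compiled session likelihood kernels.

Model fitting evaluates per-session log-likelihoods thousands of times inside
grid search and quasi-Newton polishing, so the sequential trial loops live
here as jitted kernels.  The readable NumPy step functions in
:mod:`chasegame.chase` and :mod:`chasegame.baselines` define the same
computations operation by operation; the test suite pins kernel and step
implementations against each other (and against an independent transcription
oracle) to 1e-12.

All kernels share the conventions:

- ``acts_s`` / ``acts_o``: int64 arrays of own / opponent action indices;
- ``blocks``: int64 array of block ids, state resets whenever the id changes;
- ``pi``: float64 payoff matrix (already loss-scaled where applicable);
- per-trial choice probabilities are floored at ``P_FLOOR`` before ``log``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

P_FLOOR = 1e-12


@njit(cache=True)
def softmax_t(x, temp):
    """Stabilized softmax with inverse temperature; temp == 0 gives uniform."""
    n = x.shape[0]
    out = np.empty(n)
    if temp == 0.0:
        for i in range(n):
            out[i] = 1.0 / n
        return out
    m = temp * x[0]
    for i in range(1, n):
        v = temp * x[i]
        if v > m:
            m = v
    s = 0.0
    for i in range(n):
        out[i] = np.exp(temp * x[i] - m)
        s += out[i]
    for i in range(n):
        out[i] /= s
    return out


@njit(cache=True)
def level_pred(k, a_self, a_opp, pi, beta, self_play):
    """Level-k policy by recursive best response.

    The level-0 base alternates by parity: even levels are self-referential,
    odd levels other-referential (from the stated perspective).  ``self_play``
    True gives the agent's own level-k policy; False gives its prediction of
    a level-k opponent.
    """
    if (k % 2 == 0) == self_play:
        base = a_self
    else:
        base = a_opp
    p = softmax_t(base, beta)
    for _ in range(k):
        p = softmax_t(np.dot(pi, p), beta)
    return p


@njit(cache=True)
def chase_session(acts_s, acts_o, blocks, pi, alpha, beta, gamma, kappa):
    """Full CHASE trajectory over a session.

    Returns (loglik, own_policies, pred_opp, beliefs_prior, beliefs_post,
    cv, ape, bu).  Beliefs span opponent levels 0..kappa-1; all state resets
    to uniform at every block boundary.
    """
    T = acts_s.shape[0]
    n = pi.shape[0]
    own_pols = np.zeros((T, n))
    pred_opps = np.zeros((T, n))
    b_prior = np.zeros((T, kappa))
    b_post = np.zeros((T, kappa))
    cv = np.zeros(T)
    ape = np.zeros(T)
    bu = np.zeros(T)
    a_self = np.full(n, 1.0 / n)
    a_opp = np.full(n, 1.0 / n)
    b = np.full(kappa, 1.0 / kappa)
    ll = 0.0
    for t in range(T):
        if t == 0 or blocks[t] != blocks[t - 1]:
            a_self = np.full(n, 1.0 / n)
            a_opp = np.full(n, 1.0 / n)
            b = np.full(kappa, 1.0 / kappa)
        s = acts_s[t]
        o = acts_o[t]
        # per-level predictions of the opponent's action (pre-trial state)
        preds = np.zeros((kappa, n))
        for k in range(kappa):
            preds[k] = level_pred(k, a_self, a_opp, pi, beta, False)
        # belief-weighted integrated prediction and noisy best response
        pred = np.zeros(n)
        for k in range(kappa):
            for j in range(n):
                pred[j] += b[k] * preds[k, j]
        ev = np.dot(pi, pred)
        pol = softmax_t(ev, beta)
        p = pol[s]
        if p < P_FLOOR:
            p = P_FLOOR
        ll += np.log(p)
        own_pols[t] = pol
        pred_opps[t] = pred
        b_prior[t] = b
        cv[t] = ev[s]
        # feedback: prediction error and belief update on the observed action
        ape[t] = 1.0 - pred[o]
        lik = np.empty(kappa)
        for k in range(kappa):
            lik[k] = preds[k, o]
        lhat = softmax_t(lik, gamma)
        bn = np.empty(kappa)
        z = 0.0
        for k in range(kappa):
            # floor keeps the update nondegenerate under extreme sensitivity
            lh = lhat[k] if lhat[k] > 1e-300 else 1e-300
            bn[k] = lh * b[k]
            z += bn[k]
        z2 = 0.0
        for k in range(kappa):
            bn[k] /= z
            if bn[k] < 1e-300:
                bn[k] = 1e-300
            z2 += bn[k]
        d = 0.0
        for k in range(kappa):
            bn[k] /= z2
            d += bn[k] * np.log(bn[k] / b[k])
        bu[t] = d if d > 0.0 else 0.0  # KL >= 0; clip rounding noise
        b = bn
        b_post[t] = b
        # attraction learning from both observed actions
        for j in range(n):
            a_self[j] += alpha * ((1.0 if j == s else 0.0) - a_self[j])
            a_opp[j] += alpha * ((1.0 if j == o else 0.0) - a_opp[j])
    return ll, own_pols, pred_opps, b_prior, b_post, cv, ape, bu


@njit(cache=True)
def chase_loglik(acts_s, acts_o, blocks, pi, alpha, beta, gamma, kappa):
    ll, _, _, _, _, _, _, _ = chase_session(
        acts_s, acts_o, blocks, pi, alpha, beta, gamma, kappa
    )
    return ll


@njit(cache=True)
def rl_session(acts_s, acts_o, blocks, pi, alpha, beta, decay_unchosen):
    """Reinforcement-learning (delta rule on realized payoffs) session.

    Literal vector form: q <- q + alpha * (payoff * I(chosen) - q), so
    unchosen values decay toward zero.  ``decay_unchosen`` False restricts
    the update to the chosen entry.
    """
    T = acts_s.shape[0]
    n = pi.shape[0]
    pols = np.zeros((T, n))
    q = np.zeros(n)
    ll = 0.0
    for t in range(T):
        if t == 0 or blocks[t] != blocks[t - 1]:
            q = np.zeros(n)
        s = acts_s[t]
        o = acts_o[t]
        pol = softmax_t(q, beta)
        p = pol[s]
        if p < P_FLOOR:
            p = P_FLOOR
        ll += np.log(p)
        pols[t] = pol
        payoff = pi[s, o]
        if decay_unchosen:
            for j in range(n):
                tgt = payoff if j == s else 0.0
                q[j] += alpha * (tgt - q[j])
        else:
            q[s] += alpha * (payoff - q[s])
    return ll, pols


@njit(cache=True)
def ewa_session(acts_s, acts_o, blocks, pi, delta, phi, rho, beta):
    """Experience-weighted attraction session.

    a <- (phi * n * a + [delta + (1-delta) I(chosen)] * foregone) / n'
    with n' = rho * n + 1; attractions start at the value of play against a
    uniform opponent (zero in the zero-sum game), experience at zero.
    """
    T = acts_s.shape[0]
    n_act = pi.shape[0]
    pols = np.zeros((T, n_act))
    a = np.zeros(n_act)
    nexp = 0.0
    ll = 0.0
    for t in range(T):
        if t == 0 or blocks[t] != blocks[t - 1]:
            a = np.zeros(n_act)
            nexp = 0.0
        s = acts_s[t]
        o = acts_o[t]
        pol = softmax_t(a, beta)
        p = pol[s]
        if p < P_FLOOR:
            p = P_FLOOR
        ll += np.log(p)
        pols[t] = pol
        nnew = rho * nexp + 1.0
        for j in range(n_act):
            brk = delta + (1.0 - delta) * (1.0 if j == s else 0.0)
            a[j] = (phi * nexp * a[j] + brk * pi[j, o]) / nnew
        nexp = nnew
    return ll, pols


@njit(cache=True)
def stewa_session(acts_s, acts_o, blocks, pi, beta, window):
    """Self-tuning EWA: phi is a change detector, delta an attention function.

    phi(t) = 1 - 0.5 * sum_j (h_j - r_j)^2 with h the cumulative and r the
    recent-window opponent action frequencies; delta_j = 1 iff the foregone
    payoff of j weakly exceeds the realized payoff.  rho = phi(t); only beta
    is a free parameter.
    """
    T = acts_s.shape[0]
    n_act = pi.shape[0]
    pols = np.zeros((T, n_act))
    a = np.zeros(n_act)
    nexp = 0.0
    counts = np.zeros(n_act)
    recent = np.zeros(window, dtype=np.int64)
    tcount = 0
    ll = 0.0
    for t in range(T):
        if t == 0 or blocks[t] != blocks[t - 1]:
            a = np.zeros(n_act)
            nexp = 0.0
            counts = np.zeros(n_act)
            tcount = 0
        s = acts_s[t]
        o = acts_o[t]
        pol = softmax_t(a, beta)
        p = pol[s]
        if p < P_FLOOR:
            p = P_FLOOR
        ll += np.log(p)
        pols[t] = pol
        # change detector from opponent-history mismatch (incl. this trial)
        counts[o] += 1.0
        recent[tcount % window] = o
        tcount += 1
        wlen = window if tcount >= window else tcount
        surprise = 0.0
        for j in range(n_act):
            h = counts[j] / tcount
            rj = 0.0
            for w in range(wlen):
                idx = (tcount - 1 - w) % window
                if recent[idx] == j:
                    rj += 1.0
            rj /= wlen
            surprise += (h - rj) ** 2
        phi_t = 1.0 - 0.5 * surprise
        realized = pi[s, o]
        nnew = phi_t * nexp + 1.0
        for j in range(n_act):
            dj = 1.0 if pi[j, o] >= realized else 0.0
            a[j] = (phi_t * nexp * a[j] + dj * pi[j, o]) / nnew
        nexp = nnew
    return ll, pols


@njit(cache=True)
def tie_argmax(x):
    """Distribution with mass split uniformly over maximizers (tol 1e-12)."""
    n = x.shape[0]
    m = x[0]
    for i in range(1, n):
        if x[i] > m:
            m = x[i]
    out = np.zeros(n)
    cnt = 0
    for i in range(n):
        if x[i] >= m - 1e-12:
            out[i] = 1.0
            cnt += 1
    for i in range(n):
        out[i] /= cnt
    return out


@njit(cache=True)
def tomk_trial(attr_self, attr_opp, c, k, pi, beta, c_fixed):
    """One ToMk decision: expected values and opponent predictions.

    Returns (policy, preds) where preds[m-1] is the (tie-split) argmax
    prediction of the opponent's action made at reasoning level m = 1..k.
    The simulated opponent hierarchy uses fixed confidences ``c_fixed``;
    the agent's own mixture uses the learned confidences ``c``.
    """
    n = pi.shape[0]
    f_self = np.dot(pi, attr_opp)  # agent's level-0 EV
    f_opp = np.dot(pi, attr_self)  # opponent's level-0 EV (responds to our freqs)
    ev = f_self.copy()
    preds = np.zeros((k, n))
    for m in range(1, k + 1):
        pred = tie_argmax(f_opp)
        preds[m - 1] = pred
        br = np.dot(pi, pred)
        for j in range(n):
            ev[j] = c[m - 1] * br[j] + (1.0 - c[m - 1]) * ev[j]
        if m < k:
            pred_self = tie_argmax(f_self)
            new_self = np.dot(pi, pred)
            new_opp = np.dot(pi, pred_self)
            for j in range(n):
                f_self[j] = c_fixed * new_self[j] + (1.0 - c_fixed) * f_self[j]
                f_opp[j] = c_fixed * new_opp[j] + (1.0 - c_fixed) * f_opp[j]
    return softmax_t(ev, beta), preds


@njit(cache=True)
def tomk_update_conf(c, preds, o, alpha):
    """Lowest-level credit assignment for the confidence vector.

    The lowest level whose prediction covers the observed action is updated
    positively; higher levels that also predicted it stay constant; all other
    levels decay.
    """
    k = c.shape[0]
    lowest = -1
    for m in range(k):
        if preds[m, o] > 0.0:
            lowest = m
            break
    for m in range(k):
        if m == lowest:
            c[m] = (1.0 - alpha) * c[m] + alpha
        elif lowest >= 0 and m > lowest and preds[m, o] > 0.0:
            pass  # explained by a lower level: confidence unchanged
        else:
            c[m] = (1.0 - alpha) * c[m]
    return c


@njit(cache=True)
def tomk_session(acts_s, acts_o, blocks, pi, alpha, beta, k, c_fixed, c0):
    T = acts_s.shape[0]
    n = pi.shape[0]
    pols = np.zeros((T, n))
    attr_self = np.full(n, 1.0 / n)
    attr_opp = np.full(n, 1.0 / n)
    c = np.full(k, c0)
    ll = 0.0
    for t in range(T):
        if t == 0 or blocks[t] != blocks[t - 1]:
            attr_self = np.full(n, 1.0 / n)
            attr_opp = np.full(n, 1.0 / n)
            c = np.full(k, c0)
        s = acts_s[t]
        o = acts_o[t]
        pol, preds = tomk_trial(attr_self, attr_opp, c, k, pi, beta, c_fixed)
        p = pol[s]
        if p < P_FLOOR:
            p = P_FLOOR
        ll += np.log(p)
        pols[t] = pol
        c = tomk_update_conf(c, preds, o, alpha)
        for j in range(n):
            attr_self[j] += alpha * ((1.0 if j == s else 0.0) - attr_self[j])
            attr_opp[j] += alpha * ((1.0 if j == o else 0.0) - attr_opp[j])
    return ll, pols
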