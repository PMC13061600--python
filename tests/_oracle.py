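"""Literal, single-purpose transcription of the CHASE update equations.

Deliberately naive and independent of the package implementation: plain
Python loops, its own softmax, its own payoff construction.  Used only as a
reference oracle in tests.
"""

import math

import numpy as np


def _softmax(x, temp):
    n = len(x)
    if temp == 0.0:
        return [1.0 / n] * n
    m = max(temp * v for v in x)
    e = [math.exp(temp * v - m) for v in x]
    s = sum(e)
    return [v / s for v in e]


def _payoff(n, lam):
    # action i beats j iff i == j+1 (mod n); losses scaled by lam
    pi = [[0.0] * n for _ in range(n)]
    for j in range(n):
        pi[(j + 1) % n][j] = 1.0
        pi[j][(j + 1) % n] = -lam
    return pi


def _matvec(pi, p):
    return [sum(pi[i][j] * p[j] for j in range(len(p))) for i in range(len(pi))]


def _opp_level_policy(k, a_self, a_opp, pi, beta):
    # predicting a level-k opponent: even k grounds in the opponent's own
    # history (a_opp from our perspective), odd k in ours (a_self)
    base = a_opp if k % 2 == 0 else a_self
    p = _softmax(base, beta)
    for _ in range(k):
        p = _softmax(_matvec(pi, p), beta)
    return p


def chase_oracle(acts_s, acts_o, blocks, n_actions, alpha, beta, gamma, lam, kappa):
    """Replay a session; returns dict of loglik and per-trial traces."""
    pi = _payoff(n_actions, lam)
    T = len(acts_s)
    out = {
        "loglik": 0.0,
        "beliefs": np.zeros((T, kappa)),
        "cv": np.zeros(T),
        "ape": np.zeros(T),
        "bu": np.zeros(T),
        "own_policy": np.zeros((T, n_actions)),
    }
    a_self = a_opp = b = None
    for t in range(T):
        if t == 0 or blocks[t] != blocks[t - 1]:
            a_self = [1.0 / n_actions] * n_actions
            a_opp = [1.0 / n_actions] * n_actions
            b = [1.0 / kappa] * kappa
        s, o = acts_s[t], acts_o[t]
        preds = [_opp_level_policy(k, a_self, a_opp, pi, beta) for k in range(kappa)]
        pred = [
            sum(b[k] * preds[k][j] for k in range(kappa)) for j in range(n_actions)
        ]
        ev = _matvec(pi, pred)
        pol = _softmax(ev, beta)
        out["loglik"] += math.log(max(pol[s], 1e-12))
        out["own_policy"][t] = pol
        out["cv"][t] = ev[s]
        out["ape"][t] = 1.0 - pred[o]
        lik = [preds[k][o] for k in range(kappa)]
        lhat = _softmax(lik, gamma)
        post = [lhat[k] * b[k] for k in range(kappa)]
        z = sum(post)
        post = [v / z for v in post]
        out["bu"][t] = sum(
            post[k] * math.log(post[k] / b[k]) for k in range(kappa) if post[k] > 0
        )
        b = post
        out["beliefs"][t] = b
        a_self = [
            a + alpha * ((1.0 if j == s else 0.0) - a) for j, a in enumerate(a_self)
        ]
        a_opp = [
            a + alpha * ((1.0 if j == o else 0.0) - a) for j, a in enumerate(a_opp)
        ]
    return out
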