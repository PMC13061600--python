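"""Maximum-likelihood fitting of registered models to session logs.

One parameter set is fitted per participant across all blocks and
opponents.  Continuous parameters are optimized on an unconstrained
transformed scale (logit for rates in (0, 1), log for positives) by an
initial grid search followed by quasi-Newton polishing of the best grid
points; discrete parameters (kappa for CHASE, k for ToMk) are enumerated
exhaustively.  Model comparison downstream uses AIC = 2p - 2logL, with
discrete parameters counted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .baselines import ModelSpec, get_model
from .sessions import SessionLog

__all__ = ["FitSettings", "FitResult", "aic", "fit_participant", "fit_cohort"]


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion: 2 * n_params - 2 * loglik."""
    return 2.0 * n_params - 2.0 * loglik


def to_transformed(value: float, transform: str) -> float:
    """Natural -> unconstrained scale. Transforms: "logit" for rates in
    (0, 1), "log" for positives, "range:LO:HI" for a bounded interval
    (scaled logit), "identity"."""
    if transform == "logit":
        return float(logit(np.clip(value, 1e-10, 1 - 1e-10)))
    if transform == "log":
        return float(np.log(max(value, 1e-10)))
    if transform.startswith("range:"):
        lo, hi = (float(x) for x in transform.split(":")[1:])
        u = np.clip((value - lo) / (hi - lo), 1e-10, 1 - 1e-10)
        return float(logit(u))
    if transform == "identity":
        return float(value)
    raise ValueError(f"unknown transform {transform!r}")


def from_transformed(value: float, transform: str) -> float:
    if transform == "logit":
        return float(expit(value))
    if transform == "log":
        # cap so products of transformed quantities stay finite downstream
        return float(np.exp(np.clip(value, -50, 50)))
    if transform.startswith("range:"):
        lo, hi = (float(x) for x in transform.split(":")[1:])
        return float(lo + (hi - lo) * expit(value))
    if transform == "identity":
        return float(value)
    raise ValueError(f"unknown transform {transform!r}")


@dataclass(frozen=True)
class FitSettings:
    """Optimizer configuration.

    ``max_grid`` caps the number of crossed grid start evaluations;
    ``n_polish`` grid points are refined with BFGS on the transformed scale.
    """

    n_polish: int = 3
    max_grid: int = 200
    tol: float = 1e-6
    maxiter: int = 300


@dataclass
class FitResult:
    """Per-participant maximum-likelihood fit."""

    model: str
    params: dict
    loglik: float
    aic: float
    n_params: int
    converged: bool
    n_restarts: int
    best_grid_point: dict = field(default_factory=dict)


def _neg_loglik_fn(spec: ModelSpec, session: SessionLog, discrete: dict):
    names = list(spec.continuous)
    transforms = [spec.continuous[p][0] for p in names]

    def nll(x: np.ndarray) -> float:
        params = {
            p: from_transformed(v, tr) for p, v, tr in zip(names, x, transforms)
        }
        params.update(discrete)
        try:
            return -spec.loglik(session, params)
        except FloatingPointError:
            return np.inf

    return nll, names, transforms


def _fit_discrete_combo(
    spec: ModelSpec, session: SessionLog, discrete: dict, settings: FitSettings
):
    nll, names, transforms = _neg_loglik_fn(spec, session, discrete)
    grids = [spec.continuous[p][1] for p in names]
    points = list(itertools.product(*grids))
    if len(points) > settings.max_grid:
        # deterministic thinning of an over-large grid cross
        stride = int(np.ceil(len(points) / settings.max_grid))
        points = points[::stride]
    evals = []
    for pt in points:
        x0 = np.array([to_transformed(v, tr) for v, tr in zip(pt, transforms)])
        evals.append((nll(x0), x0, pt))
    evals.sort(key=lambda e: e[0])
    best_val, best_x, best_pt = evals[0]
    converged = False
    for val, x0, _ in evals[: settings.n_polish]:
        res = minimize(
            nll, x0, method="BFGS",
            options={"maxiter": settings.maxiter, "gtol": settings.tol},
        )
        if res.fun < best_val:
            best_val, best_x = res.fun, res.x
            converged = converged or bool(res.success)
        elif res.success:
            converged = True
    params = {
        p: from_transformed(v, tr) for p, v, tr in zip(names, best_x, transforms)
    }
    params.update(discrete)
    grid_point = dict(zip(names, best_pt))
    return -best_val, params, converged, grid_point


def fit_participant(
    model: str | ModelSpec,
    session: SessionLog,
    settings: FitSettings | None = None,
) -> FitResult:
    """Grid-then-polish maximum-likelihood fit of one model to one participant.

    The returned log-likelihood is never worse than the best grid point.
    Raises ``RuntimeError`` if every start fails.
    """
    spec = get_model(model) if isinstance(model, str) else model
    settings = settings or FitSettings()
    combos = (
        [dict(zip(spec.discrete, vals)) for vals in itertools.product(
            *spec.discrete.values()
        )]
        if spec.discrete
        else [{}]
    )
    best = None
    n_restarts = 0
    for discrete in combos:
        ll, params, converged, grid_point = _fit_discrete_combo(
            spec, session, discrete, settings
        )
        n_restarts += settings.n_polish
        if not np.isfinite(ll):
            continue
        if best is None or ll > best[0]:
            best = (ll, params, converged, grid_point)
    if best is None:
        raise RuntimeError(
            f"fit failed for model {spec.name!r} on participant "
            f"{session.participant!r}: no finite likelihood found"
        )
    ll, params, converged, grid_point = best
    return FitResult(
        model=spec.name,
        params=params,
        loglik=ll,
        aic=aic(ll, spec.n_params),
        n_params=spec.n_params,
        converged=converged,
        n_restarts=n_restarts,
        best_grid_point=grid_point,
    )


def fit_cohort(
    models: list[str],
    sessions: list[SessionLog],
    settings: FitSettings | None = None,
) -> pd.DataFrame:
    """Fit several models to every session; tidy per-(participant, model) rows."""
    rows = []
    for session in sessions:
        for model in models:
            res = fit_participant(model, session, settings)
            row = {
                "participant": session.participant,
                "model": model,
                "loglik": res.loglik,
                "aic": res.aic,
                "n_params": res.n_params,
                "converged": res.converged,
            }
            row.update({f"param_{k}": v for k, v in res.params.items()})
            rows.append(row)
    return pd.DataFrame(rows)
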