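"""Cox proportional-hazards engine.

Fits the partial likelihood by Newton-Raphson (Efron or Breslow tie
handling), estimates the Breslow baseline cumulative hazard, and predicts
conditional event probabilities ``1 - exp(-Lambda0(t) * exp(z'beta))`` at
arbitrary times and counterfactual exposure levels.  The fit also carries
per-subject score residuals and the baseline estimator's building blocks
(S0, risk-set means, cumulative-hazard increments), which the
standardization module turns into sandwich variances.

Conventions: the baseline cumulative hazard is a right-continuous step
function (a prediction at t equal to an event time includes that event's
increment); the baseline uses the Breslow estimator regardless of the tie
method used for the partial likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formula import (
    DesignInfo,
    SurvivalSpec,
    build_design,
    counterfactual_design,
    drop_missing,
)

logger = logging.getLogger(__name__)

_MAXITER = 100
_TOL = 1e-10


@dataclass
class CoxFit:
    """Fitted Cox model plus the ingredients for sandwich variances.

    ``baseline_times`` / ``baseline_increments`` are the ordered event times
    and the Breslow increments d Lambda0; ``score_residuals`` is the
    (n, p) matrix of per-subject partial-likelihood score contributions in
    the original row order; ``bread`` is the inverse observed information.
    """

    spec: SurvivalSpec
    beta: np.ndarray
    design_info: DesignInfo
    baseline_times: np.ndarray
    baseline_increments: np.ndarray
    score_residuals: np.ndarray
    bread: np.ndarray
    n: int
    loglik: float
    data: pd.DataFrame
    # internals for influence-function variance (original row order)
    _s0_at_events: np.ndarray = None
    _ebar_at_events: np.ndarray = None
    _risk_score: np.ndarray = None  # exp(eta_i) at observed covariates

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.design_info.column_names)

    @property
    def max_time(self) -> float:
        return float(self.data[self.spec.time].max())

    def cumhaz(self, times) -> np.ndarray:
        """Breslow baseline cumulative hazard Lambda0 at given times."""
        times = np.asarray(times, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(self.baseline_increments)])
        idx = np.searchsorted(self.baseline_times, times, side="right")
        return cum[idx]


def _pl_derivs(X, time, event, beta, ties):
    """Log partial likelihood, gradient and observed information.

    Arrays must be sorted by ascending time.  Vectorized over event times;
    tie groups (rare with continuous times) get an Efron correction loop.
    """
    n, p = X.shape
    r = np.exp(X @ beta)
    # reverse cumulative sums: rc*(i) = sum over rows j >= i
    rc0 = np.cumsum(r[::-1])[::-1]
    rc1 = np.cumsum((X * r[:, None])[::-1], axis=0)[::-1]
    xxr = X[:, :, None] * X[:, None, :] * r[:, None, None]
    rc2 = np.cumsum(xxr[::-1], axis=0)[::-1]

    ev_idx = np.flatnonzero(event == 1)
    if ev_idx.size == 0:
        raise ValueError("no events in the data")
    ev_times = time[ev_idx]
    uniq, first = np.unique(ev_times, return_index=True)
    # index of first at-risk row for each unique event time
    risk_start = np.searchsorted(time, uniq, side="left")
    counts = np.diff(np.append(first, ev_times.size))

    S0 = rc0[risk_start]
    S1 = rc1[risk_start]
    S2 = rc2[risk_start]
    d = counts.astype(float)

    eta_events = (X[ev_idx] @ beta).sum()
    xsum_events = X[ev_idx].sum(axis=0)

    loglik = eta_events - np.sum(d * np.log(S0))
    grad = xsum_events - (d[:, None] * S1 / S0[:, None]).sum(axis=0)
    ebar = S1 / S0[:, None]
    info = np.einsum("u,uij->ij", d, S2 / S0[:, None, None]) - np.einsum(
        "u,ui,uj->ij", d, ebar, ebar
    )

    if ties == "efron":
        for k in np.flatnonzero(counts > 1):
            dk = int(counts[k])
            tied = ev_idx[first[k] : first[k] + dk]
            s0d, s1d = r[tied].sum(), (X[tied] * r[tied, None]).sum(axis=0)
            s2d = np.einsum("ni,nj->ij", X[tied] * r[tied, None], X[tied])
            # remove the Breslow contribution for this group
            loglik += dk * np.log(S0[k])
            grad += dk * S1[k] / S0[k]
            info -= dk * (S2[k] / S0[k] - np.outer(ebar[k], ebar[k]))
            frac = np.arange(dk) / dk
            s0l = S0[k] - frac * s0d
            s1l = S1[k][None, :] - frac[:, None] * s1d[None, :]
            s2l = S2[k][None, :, :] - frac[:, None, None] * s2d[None, :, :]
            loglik -= np.log(s0l).sum()
            grad -= (s1l / s0l[:, None]).sum(axis=0)
            el = s1l / s0l[:, None]
            info += np.einsum("lij->ij", s2l / s0l[:, None, None]) - np.einsum(
                "li,lj->ij", el, el
            )
    return loglik, grad, info


def _newton(Xs, ts, es, ties):
    """Newton-Raphson on the partial likelihood (arrays sorted by time)."""
    beta = np.zeros(Xs.shape[1])
    ll, grad, info = _pl_derivs(Xs, ts, es, beta, ties)
    for _ in range(_MAXITER):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(f"singular information matrix in Cox fit: {err}") from err
        # step-halving line search
        for half in range(31):
            cand = beta + step / 2**half
            ll_new, grad_new, info_new = _pl_derivs(Xs, ts, es, cand, ties)
            if ll_new >= ll - 1e-12:
                break
        else:  # pragma: no cover - pathological
            raise RuntimeError("Cox fit: step-halving failed")
        rel = abs(ll_new - ll) / (abs(ll) + 1e-10)
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if rel < _TOL and np.max(np.abs(grad)) < 1e-6 * max(1.0, len(ts)):
            return beta, ll, grad, info
    raise RuntimeError(f"Cox fit did not converge in {_MAXITER} iterations")


def _breslow_baseline(Xs, ts, es, beta):
    """Breslow baseline: unique event times, increments, S0 and risk-set means."""
    r = np.exp(Xs @ beta)
    rc0 = np.cumsum(r[::-1])[::-1]
    rc1 = np.cumsum((Xs * r[:, None])[::-1], axis=0)[::-1]
    ev_idx = np.flatnonzero(es == 1)
    uniq, first = np.unique(ts[ev_idx], return_index=True)
    risk_start = np.searchsorted(ts, uniq, side="left")
    d = np.diff(np.append(first, ev_idx.size)).astype(float)
    S0 = rc0[risk_start]
    ebar = rc1[risk_start] / S0[:, None]
    return uniq, d / S0, S0, ebar, r


def fit_cox(data: pd.DataFrame, spec: SurvivalSpec) -> CoxFit:
    """Fit the Cox model by Newton-Raphson on the partial likelihood."""
    data = drop_missing(
        data, spec.rhs, [spec.time, spec.event], [spec.cluster] if spec.cluster else []
    )
    time = data[spec.time].to_numpy(dtype=float)
    event = data[spec.event].to_numpy()
    if not set(pd.unique(data[spec.event]).tolist()) <= {0, 1, 0.0, 1.0, True, False}:
        raise ValueError(f"event column {spec.event!r} must be 0/1")
    event = event.astype(int)
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("all follow-up times must be strictly positive and finite")
    if event.sum() == 0:
        raise ValueError("no events in the data")

    X, dinfo = build_design(
        data, spec.rhs, spec.exposure, drop_intercept=True, exposure_kind=spec.exposure_kind
    )
    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    p = X.shape[1]
    if p == 0:  # null model: baseline hazard only
        ll, grad, info = _pl_derivs(Xs, ts, es, np.zeros(0), spec.tie_method)
        beta = np.zeros(0)
    else:
        beta, ll, grad, info = _newton(Xs, ts, es, spec.tie_method)
    logger.info(
        "cox fit: n=%d, events=%d, ties=%s, loglik=%.4f",
        len(ts), int(es.sum()), spec.tie_method, ll,
    )

    # Breslow baseline and sandwich ingredients at beta-hat
    uniq, dL, S0, ebar, r = _breslow_baseline(Xs, ts, es, beta)

    # Breslow-form score residuals, computed on sorted arrays
    Lam = np.concatenate([[0.0], np.cumsum(dL)])
    B = np.concatenate([[np.zeros(p)], np.cumsum(ebar * dL[:, None], axis=0)])
    pos = np.searchsorted(uniq, ts, side="right")
    Lam_T = Lam[pos]
    B_T = B[pos]
    at_event = np.searchsorted(uniq, ts, side="left")
    ebar_T = np.zeros((len(ts), p))
    has = (at_event < len(uniq)) & es.astype(bool)
    ebar_T[has] = ebar[at_event[has]]
    U = es[:, None] * (Xs - ebar_T) - r[:, None] * (Xs * Lam_T[:, None] - B_T)

    inv = np.linalg.inv(info)
    # restore original row order
    unsort = np.empty_like(order)
    unsort[order] = np.arange(len(order))
    return CoxFit(
        spec=spec,
        beta=beta,
        design_info=dinfo,
        baseline_times=uniq,
        baseline_increments=dL,
        score_residuals=U[unsort],
        bread=inv,
        n=len(ts),
        loglik=ll,
        data=data.reset_index(drop=True),
        _s0_at_events=S0,
        _ebar_at_events=ebar,
        _risk_score=r[unsort],
    )


def predict_event_prob(fit: CoxFit, data: pd.DataFrame, exposure_value, times) -> np.ndarray:
    """(n, T) matrix of P(event by t | Z_i, X set to ``exposure_value``)."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    X = counterfactual_design(data, fit.design_info, exposure_value)
    risk = np.exp(X @ fit.beta)
    Lam = fit.cumhaz(times)
    return 1.0 - np.exp(-np.outer(risk, Lam))
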