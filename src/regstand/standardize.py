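"""Regression standardization: counterfactual probabilities with sandwich variances.

``std_glm`` turns a fitted logistic model into standardized probabilities

    theta_x = (1/|S|) * sum_{i in S} p-hat(Y=1 | X=x, Z_i),

averaging the counterfactual predictions over the empirical covariate
distribution of the standardization set S (the whole sample, or a subset
such as the factually untreated).  ``std_coxph`` is the time-to-event
analogue, producing standardized *survival* probabilities on a time grid.

Variances come from the sandwich of the stacked estimating equations: the
model score equations stacked with, per requested level x, the equation
sum_{i in S} {p(Y=1|X=x,Z_i; beta) - theta_x} = 0.  The bread is the
analytic derivative of the stacked system; the meat is the outer product of
per-unit contributions, where a unit is a cluster when a cluster column is
given (contributions summed within cluster) and a row otherwise.  For the
Cox engine the baseline-hazard component of the stack is handled through
the influence function of the Breslow estimator.

A nonparametric (cluster-)bootstrap engine is provided both as a fallback
variance estimator and as an independent check on the sandwich.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cox as _cox
from . import glm as _glm
from .cox import CoxFit, fit_cox, predict_event_prob
from .formula import FACTUAL, ModelSpec, SurvivalSpec, counterfactual_design, resolve_subset
from .glm import GlmFit, fit_glm, predict_prob, prediction_gradient

logger = logging.getLogger(__name__)


@dataclass
class StdResult:
    """Standardized probabilities over exposure levels, with joint vcov."""

    levels: list
    est: np.ndarray
    vcov: np.ndarray
    n_std: int
    subset_description: Optional[str] = None
    n_clusters: Optional[int] = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0, None))

    def level_index(self, level) -> int:
        for i, lv in enumerate(self.levels):
            if lv is level or lv == level:
                return i
        raise KeyError(f"level {level!r} not among standardized levels {self.levels}")

    def to_frame(self) -> pd.DataFrame:
        labels = ["FACTUAL" if lv is FACTUAL else lv for lv in self.levels]
        return pd.DataFrame({"level": labels, "estimate": self.est, "se": self.se})

    def to_json(self) -> dict:
        """Small stable summary: levels, estimates, SEs, sample sizes."""
        labels = ["FACTUAL" if lv is FACTUAL else lv for lv in self.levels]
        return {
            "levels": labels,
            "estimate": self.est.tolist(),
            "se": self.se.tolist(),
            "n_std": self.n_std,
            "n_clusters": self.n_clusters,
            "subset": self.subset_description,
        }


@dataclass
class StdSurvResult:
    """Standardized survival probabilities on a time grid.

    ``surv[t, x]`` is the standardized survival probability
    1 - p-hat{Y_x(t)=1}; ``vcov_by_time`` holds one levels-by-levels matrix
    per time point (no cross-time covariances).
    """

    times: np.ndarray
    levels: list
    surv: np.ndarray  # (T, K)
    vcov_by_time: list = field(default_factory=list)
    n_std: int = 0
    subset_description: Optional[str] = None
    n_clusters: Optional[int] = None

    def level_index(self, level) -> int:
        for i, lv in enumerate(self.levels):
            if lv is level or lv == level:
                return i
        raise KeyError(f"level {level!r} not among standardized levels {self.levels}")

    def se(self) -> np.ndarray:
        return np.sqrt(
            np.stack([np.clip(np.diag(v), 0, None) for v in self.vcov_by_time])
        )

    def to_frame(self) -> pd.DataFrame:
        labels = ["FACTUAL" if lv is FACTUAL else lv for lv in self.levels]
        se = self.se()
        rows = []
        for j, lv in enumerate(labels):
            for i, t in enumerate(self.times):
                rows.append((lv, t, self.surv[i, j], se[i, j]))
        return pd.DataFrame(rows, columns=["level", "time", "estimate", "se"])

    def to_json(self) -> dict:
        """Small stable summary: times, levels, survival matrix, SEs."""
        labels = ["FACTUAL" if lv is FACTUAL else lv for lv in self.levels]
        return {
            "times": self.times.tolist(),
            "levels": labels,
            "survival": self.surv.tolist(),
            "se": self.se().tolist(),
            "n_std": self.n_std,
            "n_clusters": self.n_clusters,
            "subset": self.subset_description,
        }


def _check_levels(levels) -> list:
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    return levels


def _cluster_sum(contribs: np.ndarray, cluster_ids: Optional[np.ndarray]) -> np.ndarray:
    """Sum per-row contributions within clusters (rows stay rows if None)."""
    if cluster_ids is None:
        return contribs
    df = pd.DataFrame(contribs)
    df["_c"] = cluster_ids
    return df.groupby("_c", sort=False).sum().to_numpy()


def _resolve_cluster(data: pd.DataFrame, cluster) -> Optional[np.ndarray]:
    if cluster is None:
        return None
    if isinstance(cluster, str):
        if cluster not in data.columns:
            raise ValueError(f"cluster column {cluster!r} not in data")
        return data[cluster].to_numpy()
    return np.asarray(cluster)


def std_glm(
    fit: GlmFit,
    data: Optional[pd.DataFrame] = None,
    levels: Sequence = (FACTUAL,),
    subset=None,
    cluster: Optional[str] = None,
) -> StdResult:
    """Standardized outcome probabilities from a logistic fit (plug-in estimator)."""
    if data is None:
        data = fit.data
    levels = _check_levels(levels)
    mask = resolve_subset(data, subset)
    if cluster is None and len(data) == fit.n:
        cluster = fit.spec.cluster  # spec default applies to the fit sample
    cluster_ids = _resolve_cluster(data, cluster)

    preds = [predict_prob(fit, data, lv) for lv in levels]
    est = np.array([float(p[mask].mean()) for p in preds])
    vcov = _glm_sandwich(fit, data, levels, preds, mask, cluster_ids)
    return StdResult(
        levels=levels,
        est=est,
        vcov=vcov,
        n_std=int(mask.sum()),
        subset_description=subset if isinstance(subset, str) else None,
        n_clusters=None if cluster_ids is None else len(pd.unique(cluster_ids)),
    )


def _glm_sandwich(fit, data, levels, preds, mask, cluster_ids) -> np.ndarray:
    """Sandwich for the stacked (score, standardization) system; theta block.

    When ``data`` has the same number of rows as the fit sample, rows are
    assumed to be the fit sample (score and standardization contributions
    share rows and hence co-vary).  Otherwise ``data`` is treated as an
    independent standardization sample: its rows carry only standardization
    residuals and the fit rows carry only scores.
    """
    n_fit, p = fit.score_contribs.shape
    K = len(levels)
    m = int(mask.sum())
    theta = np.array([float(pr[mask].mean()) for pr in preds])
    same_sample = len(data) == n_fit

    # bread of the stacked system (sum scale, block lower-triangular)
    A = np.zeros((p + K, p + K))
    A[:p, :p] = np.linalg.inv(fit.bread)  # summed information
    for k in range(K):
        gradp = prediction_gradient(fit, data, levels[k])
        A[p + k, :p] = -gradp[mask].sum(axis=0)
        A[p + k, p + k] = m
    # per-row contributions to the stacked estimating functions
    n_rows = n_fit if same_sample else n_fit + len(data)
    U = np.zeros((n_rows, p + K))
    U[:n_fit, :p] = fit.score_contribs
    offset = 0 if same_sample else n_fit
    for k in range(K):
        rows = np.flatnonzero(mask) + offset
        U[rows, p + k] = preds[k][mask] - theta[k]
    if cluster_ids is not None and not same_sample:
        raise ValueError(
            "cluster correction requires standardizing over the fit sample"
        )
    Uu = _cluster_sum(U, cluster_ids)
    B = Uu.T @ Uu
    Ainv = np.linalg.inv(A)
    V = Ainv @ B @ Ainv.T
    return V[p:, p:]


def variance_of_standardized(
    fit, data=None, levels=(FACTUAL,), subset=None, cluster=None, times=None
):
    """Joint sandwich vcov of standardized probabilities (internal contract).

    Dispatches on the fit type: logistic fits get the analytic stacked
    sandwich; Cox fits get the per-time influence-function sandwich (one
    matrix per time point).
    """
    if isinstance(fit, GlmFit):
        return std_glm(fit, data, levels, subset, cluster).vcov
    if isinstance(fit, CoxFit):
        if times is None:
            raise ValueError("times required for Cox standardization variance")
        return std_coxph(fit, data, levels, times, subset, cluster).vcov_by_time
    raise TypeError(f"unsupported fit type {type(fit)!r}")


def std_coxph(
    fit: CoxFit,
    data: Optional[pd.DataFrame] = None,
    levels: Sequence = (FACTUAL,),
    times: Sequence = (),
    subset=None,
    cluster: Optional[str] = None,
) -> StdSurvResult:
    """Standardized survival probabilities from a Cox fit, on a time grid."""
    if data is None:
        data = fit.data
    levels = _check_levels(levels)
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(times <= 0):
        raise ValueError("times must be strictly positive (no events can occur by t=0)")
    if np.any(times > fit.max_time):
        logger.warning(
            "times beyond the last observed follow-up (%.3g): survival held flat",
            fit.max_time,
        )
    mask = resolve_subset(data, subset)
    if cluster is None:
        cluster = fit.spec.cluster
    cluster_ids = _resolve_cluster(data, cluster)

    F = [predict_event_prob(fit, data, lv, times) for lv in levels]  # each (n, T)
    theta = np.stack([Fi[mask].mean(axis=0) for Fi in F], axis=1)  # (T, K)
    vcovs = _cox_sandwich(fit, data, levels, F, times, mask, cluster_ids)
    return StdSurvResult(
        times=times,
        levels=levels,
        surv=1.0 - theta,
        vcov_by_time=vcovs,
        n_std=int(mask.sum()),
        subset_description=subset if isinstance(subset, str) else None,
        n_clusters=None if cluster_ids is None else len(pd.unique(cluster_ids)),
    )


def _cox_sandwich(fit, data, levels, F, times, mask, cluster_ids):
    """Per-time sandwich vcov of standardized event probabilities.

    Influence of theta_x(t) decomposes into (a) the averaging residual over
    the standardization set, (b) the beta-hat influence (bread times score
    residual) through the analytic gradient of the standardization
    equation, and (c) the Breslow baseline influence at t.  The same
    matrices apply to the survival orientation (signs cancel in the outer
    product).
    """
    n = fit.n
    p = len(fit.beta)
    K = len(levels)
    m = int(mask.sum())
    T = len(times)

    # per-subject beta influence: bread @ score residual
    b = fit.score_residuals @ fit.bread.T  # (n, p)

    uniq = fit.baseline_times
    dL = fit.baseline_increments
    S0 = fit._s0_at_events
    ebar = fit._ebar_at_events
    Lam_cum = np.concatenate([[0.0], np.cumsum(dL)])
    B_cum = np.concatenate([[np.zeros(p)], np.cumsum(ebar * dL[:, None], axis=0)])
    C_cum = np.concatenate([[0.0], np.cumsum(dL / S0)])

    tvals = data[fit.spec.time].to_numpy(dtype=float)
    evs = data[fit.spec.event].to_numpy(dtype=float)
    r_obs = fit._risk_score
    # S0 at each subject's own event time (only used where evs == 1)
    at_ev = np.searchsorted(uniq, tvals, side="left")
    s0_T = np.ones(n)
    hit = (at_ev < len(uniq)) & (evs == 1)
    s0_T[hit] = S0[at_ev[hit]]

    # counterfactual designs and risk scores per level
    Xk = [counterfactual_design(data, fit.design_info, lv) for lv in levels]
    rk = [np.exp(X @ fit.beta) for X in Xk]

    t_idx = np.searchsorted(uniq, times, side="right")
    vcovs = []
    for j in range(T):
        t = times[j]
        Lam_t = Lam_cum[t_idx[j]]
        B_t = B_cum[t_idx[j]]
        # baseline influence per subject
        C_min = C_cum[np.searchsorted(uniq, np.minimum(tvals, t), side="right")]
        lam = evs * (tvals <= t) / s0_T - r_obs * C_min - b @ B_t

        # per-row contributions, each summing to the estimation error of
        # its piece: averaging residual at weight 1/m, beta and baseline
        # influences already on the sum scale
        psi = np.zeros((n, K))
        for k in range(K):
            Fk = F[k][:, j]
            theta_kt = Fk[mask].mean()
            w = (1.0 - Fk) * rk[k]  # exp(-Lam r) * r, d theta / d(Lam, eta)
            c_lam = w[mask].mean()
            c_beta = (Xk[k][mask] * w[mask, None]).mean(axis=0) * Lam_t
            psi[:, k] = b @ c_beta + c_lam * lam
            psi[mask, k] += (Fk[mask] - theta_kt) / m
        Uu = _cluster_sum(psi, cluster_ids)
        vcovs.append(Uu.T @ Uu)
    return vcovs


def bootstrap_std(
    data: pd.DataFrame,
    spec,
    levels: Sequence,
    subset=None,
    times=None,
    n_boot: int = 500,
    seed: int = 0,
    cluster: Optional[str] = None,
) -> np.ndarray:
    """Nonparametric (cluster-)bootstrap of standardized probabilities.

    Refits the model on each resample and recomputes the standardized
    estimates.  Returns an array of shape (n_boot, K) for logistic specs and
    (n_boot, T, K) for survival specs, where K = len(levels).  Resampling is
    by cluster when a cluster column is given (either in ``spec`` or via
    ``cluster``), otherwise by row.  Design matrices are built once on the
    full data and resampled at the row level, so categorical codings are
    frozen.
    """
    rng = np.random.default_rng(seed)
    cluster = cluster if cluster is not None else spec.cluster
    if cluster is not None:
        ids = data[cluster].to_numpy()
        groups = pd.Series(np.arange(len(data))).groupby(ids, sort=False).apply(
            lambda s: s.to_numpy()
        )
        group_rows = list(groups)
    else:
        group_rows = None

    mask = resolve_subset(data, subset)

    if isinstance(spec, ModelSpec):
        return _bootstrap_glm(data, spec, levels, mask, group_rows, n_boot, rng)
    if isinstance(spec, SurvivalSpec):
        if times is None:
            raise ValueError("times required to bootstrap a survival spec")
        return _bootstrap_cox(data, spec, levels, mask, np.asarray(times, float),
                              group_rows, n_boot, rng)
    raise TypeError(f"unsupported spec type {type(spec)!r}")


def _resample_rows(n, group_rows, rng):
    if group_rows is None:
        return rng.integers(0, n, size=n)
    picks = rng.integers(0, len(group_rows), size=len(group_rows))
    return np.concatenate([group_rows[g] for g in picks])


def _bootstrap_glm(data, spec, levels, mask, group_rows, n_boot, rng):
    import statsmodels.api as sm
    from scipy.special import expit

    fit = fit_glm(data, spec)
    X = counterfactual_design(fit.data, fit.design_info, FACTUAL)
    y = fit.data[spec.outcome].to_numpy(dtype=float)
    Xlev = [counterfactual_design(fit.data, fit.design_info, lv) for lv in levels]
    out = np.empty((n_boot, len(levels)))
    n = len(y)
    start = fit.beta
    for bidx in range(n_boot):
        rows = _resample_rows(n, group_rows, rng)
        mb = mask[rows]
        if not mb.any():
            out[bidx] = np.nan
            continue
        res = sm.GLM(y[rows], X[rows], family=sm.families.Binomial()).fit(
            maxiter=100, tol=1e-10, start_params=start, scale=1.0
        )
        beta = np.asarray(res.params)
        for k, Xl in enumerate(Xlev):
            out[bidx, k] = expit(Xl[rows][mb] @ beta).mean()
    return out


def _bootstrap_cox(data, spec, levels, mask, times, group_rows, n_boot, rng):
    fit = fit_cox(data, spec)
    X = counterfactual_design(fit.data, fit.design_info, FACTUAL)
    Xlev = [counterfactual_design(fit.data, fit.design_info, lv) for lv in levels]
    tvals = fit.data[spec.time].to_numpy(dtype=float)
    evs = fit.data[spec.event].to_numpy().astype(int)
    n = len(tvals)
    out = np.empty((n_boot, len(times), len(levels)))
    for bidx in range(n_boot):
        rows = _resample_rows(n, group_rows, rng)
        mb = mask[rows]
        if not mb.any() or evs[rows].sum() == 0:
            out[bidx] = np.nan
            continue
        order = np.argsort(tvals[rows], kind="stable")
        sr = rows[order]
        Xs, ts, es = X[sr], tvals[sr], evs[sr]
        beta, *_ = _cox._newton(Xs, ts, es, spec.tie_method)
        uniq, dL, *_ = _cox._breslow_baseline(Xs, ts, es, beta)
        Lam_cum = np.concatenate([[0.0], np.cumsum(dL)])
        Lam_t = Lam_cum[np.searchsorted(uniq, times, side="right")]
        for k, Xl in enumerate(Xlev):
            risk = np.exp(Xl[rows][mb] @ beta)
            out[bidx, :, k] = (1.0 - np.exp(-np.outer(risk, Lam_t))).mean(axis=0)
    return out
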