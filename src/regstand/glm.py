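"""Maximum-likelihood logistic regression with sandwich ingredients.

Fitting is delegated to the IRLS implementation in statsmodels, but the
per-observation score vectors and the bread (inverse information) matrix are
always recomputed here from the final coefficient vector, so the downstream
variance machinery never depends on backend internals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .formula import (
    DesignInfo,
    FACTUAL,
    ModelSpec,
    build_design,
    counterfactual_design,
    drop_missing,
)

logger = logging.getLogger(__name__)

_MAXITER = 100
_TOL = 1e-10


@dataclass
class GlmFit:
    """Fitted logistic regression with the pieces sandwich variances need.

    Attributes
    ----------
    beta : coefficient vector on the log-odds scale.
    design_info : recorded design-construction rules (see formula module).
    score_contribs : (n, p) matrix of per-observation scores at beta-hat.
    bread : (p, p) inverse of the summed observed information at beta-hat.
    n : number of observations used.
    loglik : maximized log-likelihood.
    """

    spec: ModelSpec
    beta: np.ndarray
    design_info: DesignInfo
    score_contribs: np.ndarray
    bread: np.ndarray
    n: int
    loglik: float
    data: pd.DataFrame

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.design_info.column_names)


def fit_glm(data: pd.DataFrame, spec: ModelSpec) -> GlmFit:
    """Fit a logistic regression model described by ``spec``.

    Rows with missing values in any referenced column are dropped (the count
    is logged).  Raises on a rank-deficient design, a non-binary outcome,
    non-convergence, or perfect separation.
    """
    data = drop_missing(data, spec.rhs, [spec.outcome], [spec.cluster] if spec.cluster else [])
    y = _validate_outcome(data[spec.outcome])
    X, dinfo = build_design(
        data, spec.rhs, spec.exposure, exposure_kind=spec.exposure_kind
    )
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=_MAXITER, tol=_TOL, scale=1.0)
    if not res.converged:
        raise RuntimeError(
            f"logistic fit did not converge in {_MAXITER} iterations "
            "(possible separation or ill-conditioned design)"
        )
    beta = np.asarray(res.params, dtype=float)
    p = expit(X @ beta)
    if np.any(p <= 1e-12) or np.any(p >= 1 - 1e-12):
        raise RuntimeError(
            "fitted probabilities numerically at 0 or 1: perfect (quasi-)separation"
        )
    # recompute scores / bread internally from beta-hat
    score = X * (y - p)[:, None]
    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    bread = np.linalg.inv(info)
    loglik = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    logger.info(
        "logistic fit: n=%d, p=%d columns, loglik=%.4f", len(y), X.shape[1], loglik
    )
    return GlmFit(
        spec=spec,
        beta=beta,
        design_info=dinfo,
        score_contribs=score,
        bread=bread,
        n=len(y),
        loglik=loglik,
        data=data.reset_index(drop=True),
    )


def _validate_outcome(col: pd.Series) -> np.ndarray:
    vals = set(pd.unique(col).tolist())
    if not vals <= {0, 1, 0.0, 1.0, True, False}:
        raise ValueError(
            f"outcome column {col.name!r} must be binary 0/1; found values {sorted(map(str, vals))}"
        )
    return col.to_numpy(dtype=float)


def predict_prob(fit: GlmFit, data: pd.DataFrame, exposure_value) -> np.ndarray:
    """Conditional outcome probabilities with the exposure set to a level.

    With ``exposure_value=FACTUAL`` each row keeps its observed exposure, so
    the result equals the model's fitted values on ``data``.  For a fixed
    level every exposure-dependent design column (main effect and
    interactions) is recomputed as if X = x for every row.
    """
    X = counterfactual_design(data, fit.design_info, exposure_value)
    return expit(X @ fit.beta)


def prediction_gradient(fit: GlmFit, data: pd.DataFrame, exposure_value) -> np.ndarray:
    """(n, p) matrix of d p_i(x) / d beta at beta-hat (for sandwich breads)."""
    X = counterfactual_design(data, fit.design_info, exposure_value)
    p = expit(X @ fit.beta)
    return X * (p * (1 - p))[:, None]
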