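"""Model specifications and counterfactual design-matrix construction.

The central device of regression standardization is predicting every
subject's outcome probability *as if* their exposure were set to a fixed
level x, while all other covariates keep their observed values.  This module
owns that device: a :class:`ModelSpec` (or :class:`SurvivalSpec`) records the
formula, the exposure column and the design-construction rules frozen at fit
time, so that counterfactual designs are rebuilt deterministically --
including every exposure-dependent column (main effects, dummy expansions
and interactions) -- by overwriting the exposure column and re-applying the
recorded rules.

The sentinel :data:`FACTUAL` requests "each subject keeps their observed
exposure"; it is an explicit enum value rather than NaN so it can never
collide with genuinely missing exposure data.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import pandas as pd
from patsy import PatsyError, build_design_matrices, dmatrix

logger = logging.getLogger(__name__)


class _Factual(enum.Enum):
    """Singleton sentinel: standardize at each subject's observed exposure."""

    FACTUAL = "FACTUAL"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "FACTUAL"


FACTUAL = _Factual.FACTUAL


@dataclass
class ModelSpec:
    """Declarative description of a binary-outcome regression model.

    Parameters
    ----------
    formula : str
        Patsy formula ``"outcome ~ term1 + C(cat) + np.exp(-0.12*count) + ..."``.
        The exposure must appear among the right-hand-side terms (possibly
        inside interactions).
    exposure : str
        Name of the exposure column in the data (the raw column, not a
        transformed design column).
    cluster : str, optional
        Column defining clusters for the sandwich variance correction.
    exposure_kind : {"auto", "binary", "categorical", "continuous"}
        Recorded for documentation/validation; "auto" infers from the data.
    """

    formula: str
    exposure: str
    cluster: Optional[str] = None
    exposure_kind: str = "auto"

    def __post_init__(self) -> None:
        if "~" not in self.formula:
            raise ValueError(f"formula {self.formula!r} must contain '~'")
        lhs, rhs = self.formula.split("~", 1)
        self.outcome: str = lhs.strip()
        self.rhs: str = rhs.strip()
        # intercept-only models are allowed (the exposure then has no effect
        # and all counterfactual levels coincide)
        if self.rhs != "1" and self.exposure not in self.rhs:
            raise ValueError(
                f"exposure {self.exposure!r} does not appear in formula RHS {self.rhs!r}"
            )


@dataclass
class SurvivalSpec:
    """Description of a Cox proportional-hazards model.

    ``formula`` may be given either as a right-hand side only
    (``"treat + age + C(size)"``) or in survival-formula style
    ``"Surv(time, event) ~ treat + age"``, in which case ``time`` / ``event``
    are parsed from the left-hand side.
    """

    formula: str
    exposure: str
    time: Optional[str] = None
    event: Optional[str] = None
    cluster: Optional[str] = None
    tie_method: str = "efron"
    exposure_kind: str = "auto"

    def __post_init__(self) -> None:
        f = self.formula
        if "~" in f:
            lhs, rhs = f.split("~", 1)
            lhs = lhs.strip()
            if lhs.startswith("Surv(") and lhs.endswith(")"):
                inner = lhs[len("Surv(") : -1]
                t, e = (s.strip() for s in inner.split(","))
                if self.time is None:
                    self.time = t
                if self.event is None:
                    self.event = e
            elif lhs:
                raise ValueError(
                    f"left-hand side {lhs!r} is not of the form Surv(time, event)"
                )
            self.rhs = rhs.strip()
        else:
            self.rhs = f.strip()
        if self.time is None or self.event is None:
            raise ValueError("time and event columns must be given")
        if self.tie_method not in ("efron", "breslow"):
            raise ValueError(f"unknown tie_method {self.tie_method!r}")
        # "1" = null model (baseline hazard only)
        if self.rhs != "1" and self.exposure not in self.rhs:
            raise ValueError(
                f"exposure {self.exposure!r} does not appear in formula RHS {self.rhs!r}"
            )


@dataclass
class DesignInfo:
    """Frozen design-construction rules, recorded at fit time.

    Wraps the patsy design info of the fitted right-hand side, remembers
    which design columns depend on the exposure, and the observed exposure
    levels (for categorical exposures these define what counterfactual
    levels are admissible).
    """

    patsy_info: Any
    exposure: str
    column_names: list[str] = field(default_factory=list)
    exposure_columns: list[str] = field(default_factory=list)
    exposure_levels: list[Any] = field(default_factory=list)
    exposure_kind: str = "auto"
    drop_intercept: bool = False

    @property
    def ncol(self) -> int:
        return len(self.column_names)


def _referenced_columns(rhs: str, outcome_cols: list[str], data: pd.DataFrame) -> list[str]:
    """Columns of `data` referenced by the formula RHS or outcome columns."""
    cols = [c for c in data.columns if c in outcome_cols]
    for c in data.columns:
        if c in cols:
            continue
        # token-level containment check; patsy handles real parsing later
        if c in rhs:
            cols.append(c)
    return cols


def drop_missing(
    data: pd.DataFrame, rhs: str, outcome_cols: list[str], extra: list[str] = ()
) -> pd.DataFrame:
    """Complete-case restriction on referenced columns, with a logged count."""
    cols = _referenced_columns(rhs, list(outcome_cols) + list(extra), data)
    mask = data[cols].notna().all(axis=1)
    n_drop = int((~mask).sum())
    if n_drop:
        logger.info("dropped %d rows with missing values in %s", n_drop, cols)
    return data.loc[mask]


def build_design(
    data: pd.DataFrame,
    rhs: str,
    exposure: str,
    *,
    drop_intercept: bool = False,
    exposure_kind: str = "auto",
) -> tuple[np.ndarray, DesignInfo]:
    """Build the design matrix and record construction rules.

    The design is built with an intercept (reference coding for
    categoricals); for Cox models the intercept column is dropped afterwards
    so that categorical codings remain reference-coded.
    """
    mat = dmatrix(rhs, data, return_type="dataframe", NA_action="raise")
    info = mat.design_info
    cols = list(mat.columns)

    # detect design columns that depend on the exposure by perturbing it
    exp_cols = _exposure_dependent_columns(data, info, exposure, cols)
    levels = _observed_levels(data[exposure])
    kind = exposure_kind
    if kind == "auto":
        kind = _infer_exposure_kind(data[exposure])

    if drop_intercept and "Intercept" in cols:
        keep = [c for c in cols if c != "Intercept"]
        X = mat[keep].to_numpy(float)
        names = keep
    else:
        X = mat.to_numpy(float)
        names = cols
    dinfo = DesignInfo(
        patsy_info=info,
        exposure=exposure,
        column_names=names,
        exposure_columns=[c for c in exp_cols if c in names],
        exposure_levels=levels,
        exposure_kind=kind,
        drop_intercept=drop_intercept,
    )
    _check_full_rank(X, names)
    return X, dinfo


def _observed_levels(s: pd.Series) -> list:
    vals = pd.unique(s.dropna())
    try:
        return sorted(vals.tolist())
    except TypeError:
        return list(vals)


def _infer_exposure_kind(s: pd.Series) -> str:
    vals = set(pd.unique(s.dropna()).tolist())
    if vals <= {0, 1}:
        return "binary"
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        return "categorical"
    if len(vals) <= 10 and all(float(v).is_integer() for v in vals):
        return "categorical"
    return "continuous"


def _exposure_dependent_columns(data, info, exposure, cols) -> list[str]:
    probe = data.head(min(len(data), 50)).copy()
    base = build_design_matrices([info], probe)[0]
    lv = _observed_levels(data[exposure])
    changed: set[str] = set()
    for x in lv[: min(len(lv), 4)]:
        mod = probe.copy()
        mod[exposure] = _broadcast_level(mod[exposure], x)
        alt = build_design_matrices([info], mod)[0]
        diff = np.any(np.asarray(base) != np.asarray(alt), axis=0)
        changed |= {cols[j] for j in np.where(diff)[0]}
    return [c for c in cols if c in changed]


def _broadcast_level(col: pd.Series, x) -> pd.Series:
    out = pd.Series([x] * len(col), index=col.index)
    return out.astype(col.dtype) if col.dtype != object else out


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[0] == 0:
        raise ValueError("empty design matrix")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        d = np.abs(np.diag(r))
        tol = d.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[j]] for j in range(len(d)) if d[j] <= tol]
        bad += [names[p] for p in piv[len(d) :]]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad}"
        )


def counterfactual_design(
    data: pd.DataFrame, dinfo: DesignInfo, exposure_value
) -> np.ndarray:
    """Design matrix with the exposure column set to ``exposure_value``.

    ``FACTUAL`` keeps each row's observed exposure.  Every design column
    that depends on the exposure (main effect, dummies, interactions) is
    recomputed, because the whole design is rebuilt from the modified data.
    """
    if exposure_value is FACTUAL:
        newdata = data
    else:
        if dinfo.exposure_kind in ("binary", "categorical") and exposure_value not in dinfo.exposure_levels:
            raise ValueError(
                f"exposure level {exposure_value!r} was not observed at fit time; "
                f"known levels: {dinfo.exposure_levels}"
            )
        newdata = data.copy()
        newdata[dinfo.exposure] = _broadcast_level(newdata[dinfo.exposure], exposure_value)
    try:
        mat = build_design_matrices(
            [dinfo.patsy_info], newdata, return_type="dataframe", NA_action="raise"
        )[0]
    except PatsyError as err:
        raise ValueError(f"cannot build counterfactual design: {err}") from err
    return mat[dinfo.column_names].to_numpy(float)


def resolve_subset(data: pd.DataFrame, subset) -> np.ndarray:
    """Resolve a subset predicate into a boolean row mask.

    Accepts ``None`` (all rows), a boolean array/Series aligned with
    ``data``, or a string expression of column comparisons evaluated with
    :meth:`pandas.DataFrame.eval` (e.g. ``"nosmoke == 0"``).
    """
    if subset is None:
        return np.ones(len(data), dtype=bool)
    if isinstance(subset, str):
        try:
            mask = data.eval(subset)
        except Exception as err:
            raise ValueError(f"cannot evaluate subset expression {subset!r}: {err}") from err
    else:
        mask = subset
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (len(data),):
        raise ValueError("subset mask length does not match data")
    if not mask.any():
        raise ValueError("subset selects no rows")
    return mask
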