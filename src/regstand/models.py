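"""Model-style front end: build from data, ``fit()``, inspect results.

`StandardizedLogit` and `StandardizedCox` follow the familiar two-object
pattern: the model object holds the data and the specification
(formula, exposure, levels to standardize at, optional subset and cluster),
``fit()`` runs the regression + standardization pipeline and returns a
results object carrying the standardized estimates, their joint
variance-covariance matrix, a ``summary()`` table, and ``effect()`` for
delta-method effect measures.

Example
-------
>>> m = StandardizedLogit.from_formula(
...     "outcome ~ exposure + C(cat3) + cont", data,
...     exposure="exposure", levels=[FACTUAL, 0], cluster="id")
>>> res = m.fit()
>>> res.effect("AF")          # attributable fraction with 95% CI
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contrasts import (
    CONTRAST_FACTORIES,
    Contrast,
    EffectCurve,
    EffectEstimate,
    estimate_effect,
    plot_effect_curve,
)
from .formula import FACTUAL, ModelSpec, SurvivalSpec
from .glm import GlmFit, fit_glm
from .cox import CoxFit, fit_cox
from .standardize import (
    StdResult,
    StdSurvResult,
    bootstrap_std,
    std_coxph,
    std_glm,
)


def _resolve_contrast(contrast, levels) -> Contrast:
    if isinstance(contrast, Contrast):
        return contrast
    if isinstance(contrast, str):
        name = contrast.upper()
        if name not in CONTRAST_FACTORIES:
            raise KeyError(
                f"unknown contrast {contrast!r}; known: {sorted(CONTRAST_FACTORIES)}"
            )
        factory = CONTRAST_FACTORIES[name]
        if name == "AF":
            non_f = [lv for lv in levels if lv is not FACTUAL]
            return factory(FACTUAL, non_f[0] if non_f else 0)
        if name == "NNT":
            non_f = [lv for lv in levels if lv is not FACTUAL]
            return factory(FACTUAL, non_f[0] if non_f else 1)
        if name == "RERI":
            return factory(*levels[:4])
        non_f = [lv for lv in levels if lv is not FACTUAL]
        if len(non_f) >= 2:
            return factory(non_f[1], non_f[0])
        return factory()
    raise TypeError("contrast must be a name or a Contrast instance")


class StandardizedLogit:
    """Standardized counterfactual risks from a logistic regression.

    Parameters
    ----------
    data : DataFrame with one row per observation.
    formula : patsy formula ``"outcome ~ exposure + C(cat) + cont"``.
    exposure : name of the exposure column.
    levels : exposure levels to standardize at; the sentinel
        :data:`FACTUAL` keeps each subject's observed exposure.  Default:
        all observed levels.
    subset : optional row predicate (string expression or boolean mask)
        restricting the standardization set, e.g. ``"exposure == 1"``.
    cluster : optional cluster column for the sandwich correction.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        formula: str,
        exposure: str,
        levels: Optional[Sequence] = None,
        subset=None,
        cluster: Optional[str] = None,
    ):
        self.data = data
        self.spec = ModelSpec(formula=formula, exposure=exposure, cluster=cluster)
        if levels is None:
            levels = sorted(pd.unique(data[exposure].dropna()).tolist())
        self.levels = list(levels)
        self.subset = subset

    from_formula = classmethod(
        lambda cls, formula, data, exposure, **kw: cls(data, formula, exposure, **kw)
    )

    def fit(
        self,
        variance: str = "sandwich",
        n_boot: int = 500,
        seed: int = 0,
    ) -> "StandardizedLogitResults":
        """Fit the logistic model and standardize.

        ``variance="sandwich"`` (default) uses the stacked-estimating-
        equation sandwich; ``variance="bootstrap"`` replaces the vcov with a
        (cluster-)bootstrap estimate using ``n_boot`` replicates.
        """
        fit = fit_glm(self.data, self.spec)
        std = std_glm(fit, fit.data, self.levels, subset=self.subset)
        if variance == "bootstrap":
            samples = bootstrap_std(
                fit.data, self.spec, self.levels, subset=self.subset,
                n_boot=n_boot, seed=seed,
            )
            std.vcov = np.cov(samples[~np.isnan(samples).any(axis=1)], rowvar=False)
        elif variance != "sandwich":
            raise ValueError(f"unknown variance engine {variance!r}")
        return StandardizedLogitResults(self, fit, std, variance)


class StandardizedLogitResults:
    """Results of a standardized logistic analysis."""

    def __init__(self, model, fit: GlmFit, std: StdResult, variance: str):
        self.model = model
        self.model_fit = fit
        self.std = std
        self.variance_engine = variance

    @property
    def est(self) -> pd.Series:
        labels = ["FACTUAL" if lv is FACTUAL else lv for lv in self.std.levels]
        return pd.Series(self.std.est, index=labels, name="estimate")

    @property
    def vcov(self) -> np.ndarray:
        return self.std.vcov

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - (1 - level) / 2)
        se = self.std.se
        return pd.DataFrame(
            {"low": self.std.est - z * se, "high": self.std.est + z * se},
            index=self.est.index,
        )

    def effect(
        self, contrast, level: float = 0.95, transform: Optional[str] = None
    ) -> EffectEstimate:
        """Delta-method effect measure, e.g. ``effect("AF")``."""
        c = _resolve_contrast(contrast, self.std.levels)
        return estimate_effect(self.std, c, level=level, transform=transform)

    def summary(self) -> str:
        df = self.std.to_frame()
        ci = self.conf_int()
        df["ci_low"], df["ci_high"] = ci["low"].to_numpy(), ci["high"].to_numpy()
        lines = [
            "Standardized outcome probabilities (logistic model)",
            f"  model:    {self.model.spec.formula}",
            f"  exposure: {self.model.spec.exposure}",
            f"  n standardized over: {self.std.n_std}"
            + (
                f" (subset: {self.std.subset_description})"
                if self.std.subset_description
                else ""
            ),
            f"  clusters: {self.std.n_clusters}" if self.std.n_clusters else "  clusters: none",
            f"  variance: {self.variance_engine}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class StandardizedCox:
    """Standardized survival curves from a Cox proportional-hazards model.

    ``formula`` may include the outcome as ``"Surv(time, event) ~ ..."`` or
    be a bare right-hand side with ``time=``/``event=`` given explicitly.
    ``times`` is the grid (strictly positive) at which to standardize.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        formula: str,
        exposure: str,
        times: Sequence[float],
        time: Optional[str] = None,
        event: Optional[str] = None,
        levels: Optional[Sequence] = None,
        subset=None,
        cluster: Optional[str] = None,
        tie_method: str = "efron",
    ):
        self.data = data
        self.spec = SurvivalSpec(
            formula=formula,
            exposure=exposure,
            time=time,
            event=event,
            cluster=cluster,
            tie_method=tie_method,
        )
        if levels is None:
            levels = sorted(pd.unique(data[exposure].dropna()).tolist())
        self.levels = list(levels)
        self.times = np.asarray(times, dtype=float)
        self.subset = subset

    from_formula = classmethod(
        lambda cls, formula, data, exposure, times, **kw: cls(
            data, formula, exposure, times, **kw
        )
    )

    def fit(
        self, variance: str = "sandwich", n_boot: int = 500, seed: int = 0
    ) -> "StandardizedCoxResults":
        fit = fit_cox(self.data, self.spec)
        std = std_coxph(fit, fit.data, self.levels, self.times, subset=self.subset)
        if variance == "bootstrap":
            samples = bootstrap_std(
                fit.data, self.spec, self.levels, subset=self.subset,
                times=self.times, n_boot=n_boot, seed=seed,
            )
            ok = ~np.isnan(samples).any(axis=(1, 2))
            std.vcov_by_time = [
                np.cov(samples[ok, i, :], rowvar=False).reshape(
                    len(self.levels), len(self.levels)
                )
                for i in range(len(self.times))
            ]
        elif variance != "sandwich":
            raise ValueError(f"unknown variance engine {variance!r}")
        return StandardizedCoxResults(self, fit, std, variance)


class StandardizedCoxResults:
    """Results of a standardized Cox analysis (time-indexed)."""

    def __init__(self, model, fit: CoxFit, std: StdSurvResult, variance: str):
        self.model = model
        self.model_fit = fit
        self.std = std
        self.variance_engine = variance

    @property
    def survival(self) -> pd.DataFrame:
        labels = ["FACTUAL" if lv is FACTUAL else lv for lv in self.std.levels]
        return pd.DataFrame(self.std.surv, index=self.std.times, columns=labels)

    def effect(
        self, contrast, level: float = 0.95, transform: Optional[str] = None
    ) -> EffectCurve:
        """Pointwise delta-method effect curve, e.g. ``effect("AF")``."""
        c = _resolve_contrast(contrast, self.std.levels)
        return estimate_effect(self.std, c, level=level, transform=transform)

    def plot_effect(self, contrast, level: float = 0.95, transform=None, ax=None):
        curve = self.effect(contrast, level=level, transform=transform)
        return plot_effect_curve(curve, ax=ax)

    def summary(self) -> str:
        df = self.std.to_frame()
        lines = [
            "Standardized survival probabilities (Cox model)",
            f"  model:    Surv({self.model.spec.time}, {self.model.spec.event}) ~ "
            f"{self.model.spec.rhs}",
            f"  exposure: {self.model.spec.exposure}",
            f"  ties:     {self.model.spec.tie_method}",
            f"  n standardized over: {self.std.n_std}"
            + (
                f" (subset: {self.std.subset_description})"
                if self.std.subset_description
                else ""
            ),
            f"  clusters: {self.std.n_clusters}" if self.std.n_clusters else "  clusters: none",
            f"  variance: {self.variance_engine}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)
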