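"""Effect measures as contrasts of standardized probabilities.

A :class:`Contrast` is a named smooth function g(p) of the vector of
standardized probabilities, with an analytic gradient for the delta method:

    var{g(p-hat)} = grad g' . vcov(p-hat) . grad g

Wald confidence intervals are computed on the identity scale
(g +- z * se) or, for positive-valued measures such as the NNT, on the log
scale and back-transformed: exp[log g +- z * se / g].

Built-in measures
-----------------
AF    attributable fraction          1 - p(Y_0=1) / p(Y=1)
NNT   number needed to treat         1 / {p(Y=1|X=0) - p(Y_1=1|X=0)}
RERI  relative excess risk due to    {p11 - p10 - p01 + p00} / p00
      interaction
RD/RR causal risk difference / ratio

Contrasts consume EVENT probabilities.  Survival standardization results
store survival probabilities; the conversion p = 1 - surv happens in exactly
one place (:func:`estimate_effect`) to prevent double-flipping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .formula import FACTUAL
from .standardize import StdResult, StdSurvResult


@dataclass
class Contrast:
    """A named effect measure g(p) with analytic gradient.

    ``required_levels`` lists, in the order g expects its arguments, the
    exposure levels (possibly :data:`FACTUAL`) to pull out of a
    standardization result.
    """

    name: str
    g: Callable[[np.ndarray], float]
    grad: Callable[[np.ndarray], np.ndarray]
    required_levels: Sequence
    transform: str = "identity"  # default CI transform


@dataclass
class EffectEstimate:
    """Point estimate, SE and Wald CI for one effect measure."""

    name: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    transform_used: str = "identity"
    time: Optional[float] = None
    warning: Optional[str] = None

    def __str__(self) -> str:
        t = f" t={self.time:g}" if self.time is not None else ""
        w = f"  [warning: {self.warning}]" if self.warning else ""
        return (
            f"{self.name}{t}: {self.estimate:.4g} (se {self.se:.3g}, "
            f"{100 * self.level:.0f}% CI {self.ci_low:.4g} to {self.ci_high:.4g}, "
            f"{self.transform_used} scale){w}"
        )


@dataclass
class EffectCurve:
    """Pointwise effect estimates over a time grid."""

    name: str
    estimates: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "measure": e.name,
                    "time": e.time,
                    "estimate": e.estimate,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "transform": e.transform_used,
                }
                for e in self.estimates
            ]
        )


# ---------------------------------------------------------------------------
# scalar measures (usable directly, and wrapped as Contrast factories below)


def af(p_factual: float, p_zero: float) -> float:
    """Attributable fraction 1 - p(Y_0=1)/p(Y=1)."""
    if p_factual == 0:
        raise ZeroDivisionError("AF undefined: factual probability is 0")
    return 1.0 - p_zero / p_factual


def nnt(p_untreated_factual: float, p_untreated_if_treated: float) -> float:
    """Number needed to treat: reciprocal risk difference among the untreated.

    A non-positive risk difference (no benefit, or harm) yields +inf or a
    negative value; callers receive a structured warning rather than an
    exception so that time curves with crossing survival do not abort.
    """
    d = p_untreated_factual - p_untreated_if_treated
    if d == 0:
        return math.inf
    return 1.0 / d


def reri(p11: float, p10: float, p01: float, p00: float) -> float:
    """Relative excess risk due to interaction (additive-scale interaction / p00)."""
    if p00 == 0:
        raise ZeroDivisionError("RERI undefined: doubly-unexposed probability is 0")
    return (p11 - p10 - p01 + p00) / p00


def risk_difference(p1: float, p0: float) -> float:
    return p1 - p0


def risk_ratio(p1: float, p0: float) -> float:
    if p0 == 0:
        raise ZeroDivisionError("risk ratio undefined: reference probability is 0")
    return p1 / p0


# ---------------------------------------------------------------------------
# Contrast factories


def af_contrast(factual=FACTUAL, unexposed=0) -> Contrast:
    def g(p):
        return af(p[0], p[1])

    def grad(p):
        return np.array([p[1] / p[0] ** 2, -1.0 / p[0]])

    return Contrast("AF", g, grad, [factual, unexposed], transform="identity")


def nnt_contrast(factual=FACTUAL, treated=1) -> Contrast:
    def g(p):
        return nnt(p[0], p[1])

    def grad(p):
        d = p[0] - p[1]
        return np.array([-1.0 / d**2, 1.0 / d**2])

    return Contrast("NNT", g, grad, [factual, treated], transform="log")


def reri_contrast(l11="11", l10="10", l01="01", l00="00") -> Contrast:
    def g(p):
        return reri(p[0], p[1], p[2], p[3])

    def grad(p):
        return np.array(
            [
                1.0 / p[3],
                -1.0 / p[3],
                -1.0 / p[3],
                (-p[0] + p[1] + p[2]) / p[3] ** 2,
            ]
        )

    return Contrast("RERI", g, grad, [l11, l10, l01, l00], transform="identity")


def risk_difference_contrast(exposed=1, unexposed=0) -> Contrast:
    return Contrast(
        "RD",
        lambda p: p[0] - p[1],
        lambda p: np.array([1.0, -1.0]),
        [exposed, unexposed],
        transform="identity",
    )


def risk_ratio_contrast(exposed=1, unexposed=0) -> Contrast:
    return Contrast(
        "RR",
        lambda p: risk_ratio(p[0], p[1]),
        lambda p: np.array([1.0 / p[1], -p[0] / p[1] ** 2]),
        [exposed, unexposed],
        transform="identity",
    )


CONTRAST_FACTORIES = {
    "AF": af_contrast,
    "NNT": nnt_contrast,
    "RERI": reri_contrast,
    "RD": risk_difference_contrast,
    "RR": risk_ratio_contrast,
}


# ---------------------------------------------------------------------------
# delta-method machinery


def _wald_ci(g: float, se: float, level: float, transform: str):
    z = norm.ppf(1 - (1 - level) / 2)
    if transform == "identity":
        return g - z * se, g + z * se
    if transform == "log":
        if not (g > 0):
            raise ValueError(
                f"log-scale CI requires a positive estimate (got {g:.4g}); "
                "use transform='identity'"
            )
        if g == math.inf:
            return math.nan, math.nan
        half = z * se / g
        return g * math.exp(-half), g * math.exp(half)
    raise ValueError(f"unknown transform {transform!r}")


def _one_estimate(contrast, p, vsub, level, transform, time=None) -> EffectEstimate:
    warning = None
    try:
        g = contrast.g(p)
    except ZeroDivisionError as err:
        raise ValueError(str(err)) from None
    if not np.isfinite(g):
        return EffectEstimate(
            contrast.name, g, math.nan, math.nan, math.nan, level,
            "identity", time, warning="zero risk difference: estimate is infinite",
        )
    grad = contrast.grad(p)
    var = float(grad @ vsub @ grad)
    se = math.sqrt(max(var, 0.0))
    used = transform
    if contrast.name == "NNT" and g <= 0:
        warning = "non-positive risk difference: treatment shows no benefit or harm"
        used = "identity"
    lo, hi = _wald_ci(g, se, level, used)
    return EffectEstimate(contrast.name, g, se, lo, hi, level, used, time, warning)


def estimate_effect(
    std,
    contrast: Contrast,
    level: float = 0.95,
    transform: Optional[str] = None,
):
    """Delta-method effect estimate(s) from a standardization result.

    For a binary-outcome :class:`StdResult`, returns one
    :class:`EffectEstimate`.  For a survival :class:`StdSurvResult`, the
    stored survival probabilities are converted to event probabilities
    (p = 1 - surv) and one pointwise estimate per time point is returned as
    an :class:`EffectCurve`.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    transform = transform if transform is not None else contrast.transform
    idx = [std.level_index(lv) for lv in contrast.required_levels]
    if isinstance(std, StdResult):
        p = std.est[idx]
        vsub = std.vcov[np.ix_(idx, idx)]
        return _one_estimate(contrast, p, vsub, level, transform)
    if isinstance(std, StdSurvResult):
        curve = EffectCurve(contrast.name)
        for i, t in enumerate(std.times):
            p = 1.0 - std.surv[i, idx]
            vsub = std.vcov_by_time[i][np.ix_(idx, idx)]
            curve.estimates.append(
                _one_estimate(contrast, p, vsub, level, transform, time=float(t))
            )
        return curve
    raise TypeError(f"unsupported standardization result {type(std)!r}")


def plot_effect_curve(curve: EffectCurve, ax=None, ylabel: Optional[str] = None):
    """Estimate (solid) with pointwise CI (dashed) versus time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = curve.to_frame()
    ax.plot(df["time"], df["estimate"], "-", color="black")
    ax.plot(df["time"], df["ci_low"], "--", color="black")
    ax.plot(df["time"], df["ci_high"], "--", color="black")
    ax.set_xlabel("time")
    ax.set_ylabel(ylabel or curve.name)
    return ax
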