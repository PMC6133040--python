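"""Effect measures: definitions, gradients, delta-method intervals."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from regstand import (
    EffectCurve,
    FACTUAL,
    af,
    af_contrast,
    estimate_effect,
    nnt,
    nnt_contrast,
    reri,
    reri_contrast,
    risk_difference,
    risk_difference_contrast,
    risk_ratio,
    risk_ratio_contrast,
)
from regstand.standardize import StdResult, StdSurvResult

probs = st.floats(min_value=0.01, max_value=0.99)


@pytest.mark.parametrize(
    "pf,p0,expected",
    [(0.05, 0.01, 0.80), (0.310, 0.257, 1 - 0.257 / 0.310), (0.4, 0.4, 0.0)],
)
def test_af_values(pf, p0, expected):
    assert af(pf, p0) == pytest.approx(expected, abs=1e-12)


def test_af_undefined_at_zero_factual():
    with pytest.raises(ZeroDivisionError):
        af(0.0, 0.1)


@pytest.mark.parametrize(
    "pu,pt,expected",
    [(0.415, 0.284, 1 / (0.415 - 0.284)), (0.5, 0.25, 4.0)],
)
def test_nnt_values(pu, pt, expected):
    assert nnt(pu, pt) == pytest.approx(expected, abs=1e-9)


def test_nnt_equal_probabilities_is_infinite():
    assert nnt(0.3, 0.3) == math.inf


@pytest.mark.parametrize(
    "p,expected",
    [((0.3, 0.2, 0.15, 0.1), 0.5)],
)
def test_reri_values(p, expected):
    assert reri(*p) == pytest.approx(expected, abs=1e-12)


def test_reri_additive_null_and_error():
    assert reri(0.25, 0.2, 0.15, 0.1) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ZeroDivisionError):
        reri(0.3, 0.2, 0.1, 0.0)


def test_risk_difference_and_ratio():
    assert risk_difference(0.3, 0.3) == 0.0
    assert risk_ratio(0.3, 0.3) == 1.0
    assert risk_difference(0.4, 0.2) == pytest.approx(0.2)
    assert risk_ratio(0.4, 0.2) == pytest.approx(2.0)
    with pytest.raises(ZeroDivisionError):
        risk_ratio(0.4, 0.0)


@given(p=st.tuples(probs, probs, probs, probs))
def test_gradients_match_central_differences(p):
    p = np.asarray(p)
    h = 1e-6
    for contrast, k in [
        (af_contrast(), 2),
        (nnt_contrast(), 2),
        (reri_contrast(), 4),
        (risk_difference_contrast(), 2),
        (risk_ratio_contrast(), 2),
    ]:
        sub = p[:k]
        if contrast.name == "NNT" and abs(sub[0] - sub[1]) < 0.05:
            continue  # keep away from the singular ridge
        ana = contrast.grad(sub)
        num = np.zeros(k)
        for j in range(k):
            up, dn = sub.copy(), sub.copy()
            up[j] += h
            dn[j] -= h
            num[j] = (contrast.g(up) - contrast.g(dn)) / (2 * h)
        np.testing.assert_allclose(ana, num, rtol=1e-4, atol=1e-6)


@given(p11=probs, p10=probs, p01=probs, p00=probs)
def test_reri_symmetric_in_exposure_roles(p11, p10, p01, p00):
    assert reri(p11, p10, p01, p00) == pytest.approx(reri(p11, p01, p10, p00))


def _std(est, vcov, levels):
    return StdResult(levels=levels, est=np.asarray(est), vcov=np.asarray(vcov), n_std=100)


def test_delta_method_variance_is_quadratic_form():
    std = _std([0.31, 0.257], [[4e-4, 1e-4], [1e-4, 6e-4]], [FACTUAL, 0])
    e = estimate_effect(std, af_contrast(FACTUAL, 0))
    g = af_contrast().grad(std.est)
    assert e.se == pytest.approx(math.sqrt(g @ std.vcov @ g), rel=1e-12)
    assert e.ci_low <= e.estimate <= e.ci_high


def test_zero_variance_gives_degenerate_interval():
    std = _std([0.3, 0.2], np.zeros((2, 2)), [FACTUAL, 0])
    e = estimate_effect(std, af_contrast(FACTUAL, 0))
    assert e.ci_low == e.estimate == e.ci_high


def test_z_quantile_from_normal_distribution():
    std = _std([0.3, 0.2], [[1e-4, 0], [0, 1e-4]], [FACTUAL, 0])
    e = estimate_effect(std, af_contrast(FACTUAL, 0), level=0.95)
    z = (e.ci_high - e.estimate) / e.se
    assert z == pytest.approx(norm.ppf(0.975), abs=1e-9)
    assert z == pytest.approx(1.959964, abs=1e-6)


def test_log_interval_positive_and_matches_formula():
    std = _std([0.415, 0.284], [[9e-4, 2e-4], [2e-4, 8e-4]], [FACTUAL, 1])
    e = estimate_effect(std, nnt_contrast(FACTUAL, 1))
    assert e.transform_used == "log"
    assert e.ci_low > 0
    z = norm.ppf(0.975)
    lo = math.exp(math.log(e.estimate) - z * e.se / e.estimate)
    assert e.ci_low == pytest.approx(lo, rel=1e-10)


def test_identity_and_log_intervals_agree_as_se_vanishes():
    std = _std([0.5, 0.25], [[1e-12, 0], [0, 1e-12]], [FACTUAL, 1])
    ident = estimate_effect(std, nnt_contrast(FACTUAL, 1), transform="identity")
    logd = estimate_effect(std, nnt_contrast(FACTUAL, 1), transform="log")
    assert ident.ci_low == pytest.approx(logd.ci_low, abs=1e-4)
    assert ident.ci_high == pytest.approx(logd.ci_high, abs=1e-4)


def test_nnt_nonpositive_difference_warns_not_raises():
    std = _std([0.2, 0.3], [[1e-4, 0], [0, 1e-4]], [FACTUAL, 1])
    e = estimate_effect(std, nnt_contrast(FACTUAL, 1))
    assert e.estimate < 0 and e.warning is not None
    assert e.transform_used == "identity"
    std_eq = _std([0.3, 0.3], [[1e-4, 0], [0, 1e-4]], [FACTUAL, 1])
    e2 = estimate_effect(std_eq, nnt_contrast(FACTUAL, 1))
    assert e2.estimate == math.inf and e2.warning is not None


def test_log_transform_rejected_for_nonpositive_estimate():
    std = _std([0.3, 0.4], [[1e-4, 0], [0, 1e-4]], [FACTUAL, 0])
    with pytest.raises(ValueError, match="identity"):
        estimate_effect(std, af_contrast(FACTUAL, 0), transform="log")


def test_missing_levels_error():
    std = _std([0.3, 0.2], np.eye(2) * 1e-4, [FACTUAL, 0])
    with pytest.raises(KeyError, match="not among"):
        estimate_effect(std, af_contrast(FACTUAL, 5))


def test_survival_result_yields_pointwise_curve():
    times = np.array([10.0, 20.0])
    surv = np.array([[0.95, 0.97], [0.90, 0.93]])  # columns FACTUAL, 0
    vc = [np.eye(2) * 1e-5, np.eye(2) * 1e-5]
    std = StdSurvResult(times=times, levels=[FACTUAL, 0], surv=surv, vcov_by_time=vc)
    curve = estimate_effect(std, af_contrast(FACTUAL, 0))
    assert isinstance(curve, EffectCurve)
    assert len(curve.estimates) == 2
    # contrasts consume event probabilities p = 1 - surv
    assert curve.estimates[0].estimate == pytest.approx(1 - 0.03 / 0.05)
    df = curve.to_frame()
    assert list(df.columns) == [
        "measure", "time", "estimate", "se", "ci_low", "ci_high", "transform",
    ]
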