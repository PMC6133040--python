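"""Standardization: plug-in estimates, subsets, sandwich and bootstrap variances."""

import numpy as np
import pandas as pd
import pytest

from regstand import (
    FACTUAL,
    ModelSpec,
    SurvivalSpec,
    fit_cox,
    fit_glm,
    predict_prob,
    std_coxph,
    std_glm,
    variance_of_standardized,
)


def two_loop_oracle(fit, data, levels, mask):
    """Independent brute force: loop rows, loop levels, average predictions."""
    out = []
    for lv in levels:
        total = 0.0
        m = 0
        for i in range(len(data)):
            row = data.iloc[[i]]
            if not mask[i]:
                continue
            total += float(predict_prob(fit, row, lv)[0])
            m += 1
        out.append(total / m)
    return np.array(out)


def test_estimates_equal_two_loop_brute_force(glm_fit):
    data = glm_fit.data.iloc[:40]
    levels = [FACTUAL, 0, 1]
    mask = np.ones(40, dtype=bool)
    std = std_glm(glm_fit, data, levels)
    np.testing.assert_allclose(std.est, two_loop_oracle(glm_fit, data, levels, mask), atol=1e-12)
    # and under a subset
    mask = (data.exposure == 1).to_numpy()
    std_sub = std_glm(glm_fit, data, levels, subset="exposure == 1")
    np.testing.assert_allclose(
        std_sub.est, two_loop_oracle(glm_fit, data, levels, mask), atol=1e-12
    )


def test_factual_standardized_equals_prevalence(glm_fit):
    std = std_glm(glm_fit, levels=[FACTUAL])
    assert std.est[0] == pytest.approx(glm_fit.data.outcome.mean(), abs=1e-8)


def test_factual_within_subset_is_subset_prevalence(glm_fit):
    """With the exposure a main effect, its score equation makes the factual
    standardized probability within the X==1 subset equal that subset's
    outcome prevalence."""
    std = std_glm(glm_fit, levels=[FACTUAL], subset="exposure == 1")
    sub = glm_fit.data.exposure == 1
    assert std.est[0] == pytest.approx(glm_fit.data.outcome[sub].mean(), abs=1e-8)


def test_saturated_model_stratum_weighted_oracle():
    rng = np.random.default_rng(5)
    df = pd.DataFrame({"x": rng.integers(0, 2, 500), "z": rng.integers(0, 2, 500)})
    df["y"] = (rng.random(500) < 0.15 + 0.25 * df.x + 0.3 * df.z).astype(int)
    fit = fit_glm(df, ModelSpec("y ~ x + z + x:z", exposure="x"))
    std = std_glm(fit, levels=[0, 1])
    for k, xv in enumerate([0, 1]):
        direct = sum(
            df[(df.x == xv) & (df.z == zv)].y.mean() * (df.z == zv).mean()
            for zv in (0, 1)
        )
        assert std.est[k] == pytest.approx(direct, abs=1e-10)


def test_intercept_only_sandwich_is_binomial_variance():
    rng = np.random.default_rng(9)
    df = pd.DataFrame({"y": (rng.random(300) < 0.3).astype(int), "x": 0})
    fit = fit_glm(df, ModelSpec("y ~ 1", exposure="x"))
    std = std_glm(fit, levels=[FACTUAL])
    p = df.y.mean()
    assert std.vcov[0, 0] == pytest.approx(p * (1 - p) / len(df), abs=1e-8)


def test_singleton_clusters_equal_unclustered(glm_fit):
    levels = [FACTUAL, 0]
    std_plain = std_glm(glm_fit, levels=levels, cluster=np.arange(glm_fit.n))
    # bypass the spec's cluster column by passing explicit singleton ids
    std_rows = std_glm(glm_fit, glm_fit.data, levels, cluster=np.arange(glm_fit.n))
    np.testing.assert_allclose(std_plain.vcov, std_rows.vcov, atol=1e-15)


def test_clustered_vcov_differs_and_is_psd(glm_fit):
    std = std_glm(glm_fit, levels=[FACTUAL, 0, 1])  # cluster from spec ("id")
    assert std.n_clusters == glm_fit.data.id.nunique()
    np.testing.assert_allclose(std.vcov, std.vcov.T, atol=1e-14)
    assert np.linalg.eigvalsh(std.vcov).min() > -1e-10
    assert np.all(np.diag(std.vcov) >= 0)
    assert np.all((std.est >= 0) & (std.est <= 1))


def test_duplicated_levels_give_identical_rows(glm_fit):
    std = std_glm(glm_fit, levels=[0, 0, 1])
    assert std.est[0] == std.est[1]
    np.testing.assert_allclose(std.vcov[0], std.vcov[1], atol=1e-14)
    np.testing.assert_allclose(std.vcov[:, 0], std.vcov[:, 1], atol=1e-14)


def test_subset_errors(glm_fit):
    with pytest.raises(ValueError, match="no rows"):
        std_glm(glm_fit, levels=[0], subset="cont > 1e9")
    with pytest.raises(ValueError, match="subset"):
        std_glm(glm_fit, levels=[0], subset="nosuchcol == 1")
    with pytest.raises(ValueError, match="non-empty"):
        std_glm(glm_fit, levels=[])


def test_stacked_bread_matches_numeric_differentiation(glm_fit):
    """Analytic derivative of the standardization equation w.r.t. beta agrees
    with central differences of the averaged prediction."""
    from scipy.special import expit

    from regstand.formula import counterfactual_design

    data = glm_fit.data
    X0 = counterfactual_design(data, glm_fit.design_info, 0)
    h = 1e-6
    num = np.zeros(len(glm_fit.beta))
    for j in range(len(glm_fit.beta)):
        bp, bm = glm_fit.beta.copy(), glm_fit.beta.copy()
        bp[j] += h * max(1, abs(glm_fit.beta[j]))
        bm[j] -= h * max(1, abs(glm_fit.beta[j]))
        num[j] = (expit(X0 @ bp).mean() - expit(X0 @ bm).mean()) / (bp[j] - bm[j])
    from regstand.glm import prediction_gradient

    ana = prediction_gradient(glm_fit, data, 0).mean(axis=0)
    np.testing.assert_allclose(ana, num, rtol=1e-4, atol=1e-8)


def test_variance_contract_dispatch(glm_fit, cox_fit):
    v = variance_of_standardized(glm_fit, levels=[FACTUAL, 0])
    assert v.shape == (2, 2)
    vs = variance_of_standardized(cox_fit, levels=[FACTUAL, 0], times=[20.0, 40.0])
    assert len(vs) == 2 and vs[0].shape == (2, 2)
    with pytest.raises(ValueError, match="times"):
        variance_of_standardized(cox_fit, levels=[0])


# --- survival ---------------------------------------------------------------


def test_cox_null_model_standardization_is_baseline(hand_survival_df):
    fit = fit_cox(hand_survival_df, SurvivalSpec("Surv(time, event) ~ 1", exposure="x"))
    times = [2.0, 4.0, 8.0]
    std = std_coxph(fit, levels=[FACTUAL, 0, 1], times=times)
    base = np.exp(-fit.cumhaz(times))
    for k in range(3):
        np.testing.assert_allclose(std.surv[:, k], base, rtol=1e-12)


def test_cox_standardized_estimates_equal_brute_force(cox_fit):
    from regstand import predict_event_prob

    times = [15.0, 45.0]
    std = std_coxph(cox_fit, levels=[FACTUAL, 0], times=times)
    for k, lv in enumerate([FACTUAL, 0]):
        F = predict_event_prob(cox_fit, cox_fit.data, lv, times)
        np.testing.assert_allclose(std.surv[:, k], 1 - F.mean(axis=0), atol=1e-12)


def test_cox_survival_monotone_and_in_range(cox_fit):
    std = std_coxph(cox_fit, levels=[FACTUAL, 0, 1], times=np.arange(5.0, 100.0, 5.0))
    assert np.all((std.surv > 0) & (std.surv <= 1))
    assert np.all(np.diff(std.surv, axis=0) <= 1e-12)


def test_cox_vcov_psd_and_symmetric(cox_fit):
    std = std_coxph(cox_fit, levels=[FACTUAL, 0, 1], times=[20.0, 50.0])
    for v in std.vcov_by_time:
        np.testing.assert_allclose(v, v.T, atol=1e-14)
        assert np.linalg.eigvalsh(v).min() > -1e-10


def test_cox_extrapolation_warns_and_holds_flat(cox_fit, caplog):
    import logging

    tmax = cox_fit.max_time
    with caplog.at_level(logging.WARNING, logger="regstand.standardize"):
        std = std_coxph(cox_fit, levels=[0], times=[tmax, tmax + 50.0])
    assert any("flat" in r.message for r in caplog.records)
    last_event = cox_fit.baseline_times.max()
    assert std.surv[1, 0] == pytest.approx(std.surv[0, 0], abs=1e-12) or last_event <= tmax


def test_cox_subset_and_cluster_paths(surv_df, surv_spec):
    fit = fit_cox(surv_df, surv_spec)
    std = std_coxph(fit, levels=[FACTUAL, 1], times=[30.0], subset="notreat == 0")
    assert std.n_std == int((surv_df.notreat == 0).sum())
    ids = np.repeat(np.arange(len(surv_df) // 2 + 1), 2)[: len(surv_df)]
    df2 = fit.data.copy()
    df2["cid"] = ids[: len(df2)]
    std_cl = std_coxph(fit, df2, [FACTUAL, 1], times=[30.0], cluster="cid")
    assert std_cl.n_clusters == len(np.unique(df2.cid))


def test_serialization_layouts(glm_fit, cox_fit):
    std = std_glm(glm_fit, levels=[FACTUAL, 0])
    df = std.to_frame()
    assert list(df.columns) == ["level", "estimate", "se"]
    js = std.to_json()
    assert js["levels"] == ["FACTUAL", 0] and len(js["estimate"]) == 2
    sstd = std_coxph(cox_fit, levels=[FACTUAL, 0], times=[20.0, 40.0])
    sdf = sstd.to_frame()
    assert list(sdf.columns) == ["level", "time", "estimate", "se"]
    assert len(sdf) == 4
    assert len(sstd.to_json()["survival"]) == 2
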