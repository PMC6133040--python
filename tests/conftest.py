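import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from regstand import (
    BinaryGenConfig,
    ModelSpec,
    SurvivalGenConfig,
    SurvivalSpec,
    fit_cox,
    fit_glm,
    generate_binary,
    generate_survival,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


BINARY_FORMULA = "outcome ~ exposure + C(cat3) + cont"
SURV_FORMULA = "Surv(time, event) ~ notreat + age + meno + C(size) + np.exp(-0.12*nodes)"


@pytest.fixture(scope="session")
def binary_df():
    return generate_binary(BinaryGenConfig(n_clusters=150, seed=7))


@pytest.fixture(scope="session")
def binary_spec():
    return ModelSpec(BINARY_FORMULA, exposure="exposure", cluster="id")


@pytest.fixture(scope="session")
def glm_fit(binary_df, binary_spec):
    return fit_glm(binary_df, binary_spec)


@pytest.fixture(scope="session")
def surv_df():
    df = generate_survival(SurvivalGenConfig(n=600, seed=3))
    df["notreat"] = 1 - df["treat"]
    return df


@pytest.fixture(scope="session")
def surv_spec():
    return SurvivalSpec(SURV_FORMULA, exposure="notreat")


@pytest.fixture(scope="session")
def cox_fit(surv_df, surv_spec):
    return fit_cox(surv_df, surv_spec)


@pytest.fixture(scope="session")
def tiny_breslow_df():
    """Three subjects: events at t=1 and t=2, one censored at t=3."""
    return pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 0], "x": [0, 0, 0]})


@pytest.fixture(scope="session")
def hand_survival_df():
    """Six subjects with hand-countable risk sets."""
    return pd.DataFrame(
        {
            "time": [2.0, 3.0, 3.5, 5.0, 7.0, 9.0],
            "event": [1, 0, 1, 1, 0, 1],
            "x": [1, 0, 1, 0, 1, 0],
        }
    )
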