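import numpy as np
import pandas as pd
import pytest

from recurcure.data import RecurrentData
from recurcure.hazards import ModelParams, WeibullBaseline
from recurcure.simulate import SimulationConfig, simulate_dataset


def make_data(gap, delta, z, v, subject):
    """Small helper: long-format RecurrentData from plain lists."""
    df = pd.DataFrame({
        "subject_id": subject,
        "gap_time": gap,
        "event": delta,
        "z": z,
        "v": v,
    })
    return RecurrentData.from_frame(df, z_cols=["z"], v_cols=["v"])


@pytest.fixture(scope="session")
def tiny_data():
    """Two subjects, five records (three events, two censored)."""
    return make_data(
        gap=[0.5, 1.2, 2.0, 0.8, 3.0],
        delta=[1, 1, 0, 1, 0],
        z=[1.0, 1.0, 1.0, 0.0, 0.0],
        v=[0.0, 0.0, 0.0, 1.0, 1.0],
        subject=[1, 1, 1, 2, 2],
    )


@pytest.fixture(scope="session")
def weibull_params():
    return ModelParams(
        beta=np.array([0.4]),
        gamma=np.array([0.3, -0.5]),
        alpha=1.2,
        baseline=WeibullBaseline(scale=1.0, shape=1.5),
        link="cloglog",
    )


@pytest.fixture(scope="session")
def nocure_dataset():
    """Frailty PH data with the cure component switched off (pi ~ 1)."""
    cfg = SimulationConfig(gamma0=-8.0, gamma=0.0, beta=-1.0, alpha=1.0,
                           n_subjects=300)
    return simulate_dataset(cfg, seed=42)


@pytest.fixture(scope="session")
def small_cure_dataset():
    """Moderate-cure clog-log data, small enough for fast fits."""
    cfg = SimulationConfig(n_subjects=250, gamma0=1.0, gamma=-5.0, beta=-4.0,
                           alpha=0.5, weibull_scale=3.0, weibull_shape=10.0)
    return simulate_dataset(cfg, seed=17)
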