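"""Shared fixtures: small simulated datasets and direct model simulators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ehrlandmark.config import MARKERS, SynthConfig


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(seed=11, n_patients=400)


@pytest.fixture(scope="session")
def small_data(small_config):
    from ehrlandmark.synthetic import simulate

    return simulate(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_data):
    from ehrlandmark.cohort import build_cohort

    registry, measurements, _ = small_data
    return build_cohort(registry, measurements)


def simulate_mlmm_data(
    rng: np.random.Generator,
    n_patients: int,
    beta: dict[str, tuple[float, float]],
    G: np.ndarray,
    sigma2: np.ndarray,
    gamma: float = -0.4,
    mean_obs: float = 4.0,
    t_span: float = 15.0,
    bp_frac: float = 0.3,
) -> pd.DataFrame:
    """Vectorized draw from the stage-1 model on the t <= 0 scale."""
    L = np.linalg.cholesky(G + 1e-12 * np.eye(4))
    b = rng.standard_normal((n_patients, 4)) @ L.T
    bp_on = rng.random(n_patients) < bp_frac
    frames = []
    for k, m in enumerate(MARKERS):
        counts = rng.poisson(mean_obs, n_patients)
        pid = np.repeat(np.arange(n_patients), counts)
        t = -rng.random(counts.sum()) * t_span
        bp = (bp_on[pid] & (t > -5.0)).astype(int) if m == "sbp" else np.zeros(len(t), int)
        b0, b1 = beta[m]
        y = (
            b0
            + b1 * t
            + (gamma * bp if m == "sbp" else 0.0)
            + b[pid, k]
            + rng.normal(0.0, np.sqrt(sigma2[k]), len(t))
        )
        frames.append(
            pd.DataFrame(
                {"patient_id": pid, "marker": m, "t": t, "value": y, "bp_med": bp}
            )
        )
    return pd.concat(frames, ignore_index=True), b


@pytest.fixture
def mlmm_truth():
    G = np.array(
        [
            [0.15, 0.03, 0.05, -0.04],
            [0.03, 0.50, 0.10, -0.05],
            [0.05, 0.10, 0.50, -0.10],
            [-0.04, -0.05, -0.10, 0.60],
        ]
    )
    sigma2 = np.array([0.05, 0.50, 0.40, 0.30])
    beta = {
        "smoking": (0.30, -0.004),
        "sbp": (0.10, 0.030),
        "tchol": (-0.20, 0.020),
        "hdlc": (0.05, -0.005),
    }
    return beta, G, sigma2


@pytest.fixture
def cox_fixture() -> pd.DataFrame:
    """Six subjects, one binary covariate, untied event times."""
    return pd.DataFrame(
        {
            "patient_id": [1, 2, 3, 4, 5, 6],
            "practice_id": 0,
            "sex": "male",
            "s": 50,
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 0, 1, 1, 0, 1],
            "x": [1.0, 1.0, 0.0, 1.0, 0.0, 0.0],
        }
    )
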