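import numpy as np
import pandas as pd
import pytest

from melonopt import calibration_table, default_effect_spec, simulate_trial
from melonopt.grading import quality_scores_from_means
from melonopt.synthetic import RandomPlan


def treatment_labels(index) -> list[str]:
    return [f"{c}/{s:g}L/{d}p" for (c, s, d) in index]


@pytest.fixture(scope="session")
def calibration() -> pd.DataFrame:
    return calibration_table()


@pytest.fixture(scope="session")
def default_sim():
    """One deterministic default-size (503 fruit) simulated trial."""
    return simulate_trial(default_effect_spec(), RandomPlan(seed=20200129))


@pytest.fixture(scope="session")
def objective_matrix_values(calibration) -> pd.DataFrame:
    """Quality/yield/WP objective table built from the calibration fixture."""
    means = calibration[["brix", "net_score"]].copy()
    means.index = treatment_labels(calibration.index)
    quality = quality_scores_from_means(means)
    return pd.DataFrame(
        {
            "quality_score": quality,
            "total_yield": calibration["total_yield"].to_numpy(),
            "water_productivity": calibration["water_productivity"].to_numpy(),
        },
        index=means.index,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
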