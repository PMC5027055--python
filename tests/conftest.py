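import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from trendnet.matrix import ExpressionMatrix
from trendnet.stc import enumerate_profiles

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

DAYS = (0, 1, 3, 7, 21)


def make_matrix(time_means, biotypes=None, replicates=3, noise_sd=0.0, seed=0, days=DAYS):
    """Small ExpressionMatrix from a dict gene -> per-time means."""
    genes = list(time_means)
    rng = np.random.default_rng(seed)
    data = np.repeat(np.array([time_means[g] for g in genes], float), replicates, axis=1)
    if noise_sd:
        data = data + rng.normal(0, noise_sd, data.shape)
    if biotypes is None:
        biotypes = ["mRNA"] * len(genes)
    return ExpressionMatrix.from_arrays(genes, biotypes, days, data, replicates)


@pytest.fixture(scope="session")
def profiles5():
    return enumerate_profiles(5)


@pytest.fixture
def flat_noise_matrix():
    rng = np.random.default_rng(42)
    genes = [f"G{i:03d}" for i in range(40)]
    data = 8.0 + rng.normal(0, 0.3, (40, 15))
    return ExpressionMatrix.from_arrays(genes, ["mRNA"] * 40, DAYS, data, 3)
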