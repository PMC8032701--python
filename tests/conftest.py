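import numpy as np
import pytest

from actihsmm import ActivitySeries, ModelConfig
from actihsmm.likelihood import forward_log_likelihood
from actihsmm.parameters import from_unconstrained, n_unconstrained


def random_valid_params(config, rng, scale=0.6):
    """Random parameter set drawn through the unconstrained map (always valid)."""
    return from_unconstrained(rng.normal(0.0, scale, n_unconstrained(config)),
                              config)


def random_small_instance(rng, T_max=8, M_max=3, D_max=3, mean_count=2.0):
    """Random (config, params, series) with a non-degenerate duration grid.

    Draws are retried when the dwell grid carries no probability mass (a
    legitimate error path exercised separately).
    """
    while True:
        M = int(rng.integers(2, M_max + 1))
        T = int(rng.integers(3, T_max + 1))
        D = int(rng.integers(2, D_max + 1))
        config = ModelConfig(
            M=M, D_max=D, q=1, p_dim=1,
            duration_family="weibull" if rng.random() < 0.5 else "gamma")
        params = random_valid_params(config, rng)
        series = ActivitySeries(
            "sim", rng.poisson(mean_count, T),
            rng.integers(0, 2, (T, 1)).astype(float),
            rng.integers(0, 2, (T, 1)).astype(float))
        try:
            forward_log_likelihood(series, params, config)
        except ValueError:
            continue
        return config, params, series


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
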