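"""Shared fixtures: one synthetic study campaign reused across modules."""

import numpy as np
import pytest

from flcseason import (
    ObservationNoise,
    TemperatureModel,
    default_params,
    gen_observations,
    gen_temperature,
)

ZERO_NOISE = {k: 0.0 for k in ("K27_NR", "K27_DNR", "K4_NR", "K4_DNR",
                               "mRNA")}


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def temp():
    """Three-year daily temperature record with short-term fluctuations."""
    return gen_temperature(TemperatureModel(seed=1), 3)


@pytest.fixture(scope="session")
def temp_smooth():
    """Noise-free seasonal record (pure sinusoid)."""
    return gen_temperature(TemperatureModel(seed=1, noise_sd=0.0), 3)


@pytest.fixture(scope="session")
def obs_noisy(params, temp):
    """Default campaign: 2 years, biweekly, 4 replicates, 10% noise."""
    return gen_observations(params, temp, ObservationNoise(seed=2))


@pytest.fixture(scope="session")
def obs_clean(params, temp):
    """Same campaign without observation noise, single replicate."""
    return gen_observations(
        params, temp, ObservationNoise(sd=dict(ZERO_NOISE), n_replicates=1)
    )
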