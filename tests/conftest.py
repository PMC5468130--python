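import numpy as np
import pytest

from aggassay import (
    Arena,
    NullConfig,
    SamplingScheme,
    build_null_distribution,
)


@pytest.fixture(scope="session")
def arena():
    return Arena()


@pytest.fixture(scope="session")
def scheme():
    return SamplingScheme()


@pytest.fixture(scope="session")
def analysis_scheme():
    """Analysis-cadence scheme with no acclimation (null-model cadence)."""
    return SamplingScheme(
        raw_interval_s=180.0,
        analysis_interval_s=180.0,
        acclimation_frames=0,
        duration_s=180.0 * 30,
    )


@pytest.fixture(scope="session")
def null_n5(arena):
    """Study-sized CSR null for 5 individuals, shared across tests."""
    return build_null_distribution(
        NullConfig(n_individuals=5, arena=arena, n_videos=100, seed=20205)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
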