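import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

from stratovir.config import CommunityConfig


@pytest.fixture(scope="session")
def small_config() -> CommunityConfig:
    """A small but structurally complete community for fast tests."""
    return CommunityConfig(
        n_epi_specialists=6, n_hypo_specialists=4, n_generalists=4,
        n_cellular_decoys=3, genome_length_range=(60_000, 120_000),
        reads_per_sample=50_000, seed=11)


@pytest.fixture(scope="session")
def default_community_config() -> CommunityConfig:
    """The default study-scale community (60 epi / 30 hypo / 30 generalist)."""
    return CommunityConfig(seed=1234)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
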