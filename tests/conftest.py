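import numpy as np
import pytest

from hassellcomins import CommunityParams, PopulationState, SpeciesParams


@pytest.fixture
def community() -> CommunityParams:
    """Reference two-species community: unit sizes 1 and 2, mean resource 10,
    species 1 needs two units to reproduce, species 2 one."""
    return CommunityParams(
        sp1=SpeciesParams(u=1.0, s=2, lam=2.0, alpha=1.0, name="sp1"),
        sp2=SpeciesParams(u=2.0, s=1, lam=2.0, alpha=1.0, name="sp2"),
        Rbar=10.0)


@pytest.fixture
def contest_community() -> CommunityParams:
    """Both species at maximum inequality (s = 1, Beverton-Holt-like)."""
    return CommunityParams(
        sp1=SpeciesParams(u=1.0, s=1, lam=2.0, alpha=1.0),
        sp2=SpeciesParams(u=2.0, s=1, lam=2.0, alpha=1.0),
        Rbar=10.0)


@pytest.fixture
def state55() -> PopulationState:
    return PopulationState(5, 5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
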