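import numpy as np
import pytest

from cogload.synthetic import CouplingSpec


@pytest.fixture
def two_channel_independent() -> CouplingSpec:
    """Two uncoupled noisy oscillators (null-hypothesis condition)."""
    return CouplingSpec(n_channels=2, noise_sd=1.0)


@pytest.fixture
def two_channel_shared() -> CouplingSpec:
    """Channel 1 fully shares channel 0's phase component, noise-free."""
    return CouplingSpec(
        n_channels=2,
        pair_strengths=[[0, 1], [0, 0]],
        noise_sd=0.0,
        base_freqs=[10.0, 10.0],
    )


def directed_pair_spec(strength: float, lag: int = 5) -> CouplingSpec:
    """Planted directed coupling channel 0 -> channel 1 at the given lag."""
    return CouplingSpec(
        n_channels=2,
        pair_strengths=[[0, strength], [0, 0]],
        directed_lags=[[0, lag], [0, 0]],
        noise_sd=0.8,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
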