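import numpy as np
import pytest

from striatal_chunking import ChunkProtocol, ReservoirParams, init_weights


@pytest.fixture
def small_protocol() -> ChunkProtocol:
    """A 10-character alphabet with a 4-character chunk, short stream."""
    return ChunkProtocol(
        alphabet_size=10,
        chunk=(0, 1, 2, 3),
        char_duration=50.0,
        chunk_rate=0.2,
        total_duration=2_000.0,
    )


@pytest.fixture
def tiny_params() -> ReservoirParams:
    """A reservoir small enough for exhaustive checks."""
    return ReservoirParams(n_neurons=40, n_readout=40, tau=10.0, noise_std=0.3)


@pytest.fixture
def tiny_weights(tiny_params):
    return init_weights(tiny_params, n_inputs=10, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
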