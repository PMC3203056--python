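import numpy as np
import pytest

from stdplearn import (
    NeuronParams,
    PatternSpec,
    STDPParams,
    make_schedule,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_spec():
    """Twenty afferents, ten carrying the pattern; baseline rates."""
    return PatternSpec(
        model_kind="S",
        n_total=20,
        n_pattern=10,
        pattern_duration=50.0,
        presentation_rate=1.5,
        background_rate=20.0,
    ).with_random_latencies(7)


@pytest.fixture()
def short_schedule():
    return make_schedule(200_000.0, 1.5, 50.0, seed=21)


@pytest.fixture()
def stdp():
    return STDPParams()


@pytest.fixture()
def neuron():
    return NeuronParams()
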