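import numpy as np
import pytest

from selfdenoise3d import VideoStack, make_denoising_fixture


@pytest.fixture(scope="session")
def small_pair():
    """Small paired clean/noisy calcium fixture at -2.5 dB, shared across tests."""
    clean, noisy, model, manifest = make_denoising_fixture(
        -2.5, size=(64, 64, 200), seed=11
    )
    return clean, noisy, model, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_stack(rng):
    data = rng.uniform(0, 100, size=(24, 20, 30)).astype(np.float32)
    return VideoStack(data=data, name="random")
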