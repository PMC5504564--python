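import numpy as np
import pytest

from semgrecal import Recording, SynthConfig, generate_recording


@pytest.fixture(scope="session")
def tiny_config() -> SynthConfig:
    """Two classes, short blocks: fast to generate, still spectrally separable."""
    return SynthConfig(
        n_classes=2,
        n_channels=4,
        movement_duration=1.0,
        rest_duration=1.0,
        n_repetitions=2,
        class_spectra=[(100.0, 80.0), (400.0, 80.0)],
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_recording(tiny_config) -> Recording:
    return generate_recording(tiny_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
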