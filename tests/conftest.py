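import numpy as np
import pytest

from viscomfort import stimuli, v1model


@pytest.fixture(scope="session")
def ppd16() -> float:
    """Coarse calibration used for fast small-image tests (Nyquist 8 c/deg)."""
    return 16.0


@pytest.fixture(scope="session")
def small_population():
    """100-cell population with peak frequencies below the ppd16 Nyquist."""
    return v1model.sample_population(
        100, seed=3, distribution_params={"freq_range": (0.5, 6.0)}
    )


@pytest.fixture(scope="session")
def grating3(ppd16):
    return stimuli.make_grating(
        stimuli.GratingSpec(frequency=3.0, size=128, contrast=1.0), ppd16
    )


@pytest.fixture(scope="session")
def white_noise(ppd16):
    return stimuli.make_onef_noise(0.0, size=128, seed=5, ppd=ppd16)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
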