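import numpy as np
import pytest

from fiberorient import IntensityImage, SimulationConfig, simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def small_fiber_bundle():
    """A 128x128 simulated fiber image with moderate alignment and noise.

    Small enough that MC harness runs and repeated analyses stay fast, large
    enough that the power spectrum has fiber streaks with realistic dynamics.
    """
    config = SimulationConfig(
        size=(128, 128), width=3.0, aspect_ratio=15.0, k=2.0,
        theta_bar=25.0, noise_factor=0.5, seed=11,
    )
    return simulate(config)


@pytest.fixture(scope="session")
def aligned_bundle_512():
    """A clean, highly aligned full-size bundle for ground-truth recovery."""
    config = SimulationConfig(
        size=(512, 512), width=5.0, aspect_ratio=30.0, k=5.0,
        theta_bar=30.0, noise_factor=0.0, seed=42,
    )
    return simulate(config)


@pytest.fixture()
def random_image_8x8():
    values = np.random.default_rng(3).uniform(0, 200, (8, 8))
    return IntensityImage.from_counts(values)
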