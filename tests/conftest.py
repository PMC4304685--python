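import numpy as np
import pytest

from saxsqc.io_formats import ScatteringProfile
from saxsqc.simulate import sphere_profile

SPHERE_RADIUS = 30.0
SPHERE_RG = SPHERE_RADIUS * np.sqrt(3.0 / 5.0)  # 23.2379...
SPHERE_VOLUME = 4.0 / 3.0 * np.pi * SPHERE_RADIUS**3  # 113097.3


@pytest.fixture(scope="session")
def sphere30():
    """Noiseless 30 Å sphere on the default grid (session-wide, read-only)."""
    return sphere_profile(SPHERE_RADIUS)


@pytest.fixture
def noisy_sphere():
    """Factory: independent 1%-noise realizations of the 30 Å sphere."""

    def make(seed, radius=SPHERE_RADIUS, scale=1.0, sigma_fraction=0.01):
        clean = sphere_profile(radius, scale=scale)
        rng = np.random.default_rng(seed)
        sigma = sigma_fraction * clean.intensity + 1e-6 * scale
        return ScatteringProfile(
            clean.q, clean.intensity + rng.normal(0.0, sigma), sigma,
            label=f"noisy_{seed}",
        )

    return make
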