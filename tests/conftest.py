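import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phycospec as ps

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def grid204():
    """The full 204-band 400-1000 nm acquisition grid."""
    return ps.make_wavelength_grid()


@pytest.fixture(scope="session")
def small_grid():
    """A reduced 60-band grid covering the same range, for fast model tests."""
    return ps.make_wavelength_grid(60, 400, 1000)


@pytest.fixture(scope="session")
def mid_panel():
    """Mid-range pigment panel (mg/g fresh weight)."""
    return ps.PigmentPanel(6.79, 3.92, 1.44, 1.36)


@pytest.fixture(scope="session")
def lab_samples():
    """96 lab-range samples at the moderate default noise level."""
    return ps.simulate_sample_set(n=96, noise=ps.NoiseSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_small_samples(small_grid):
    """48 noiseless samples on the reduced grid, for exact-recovery checks.

    Note: with zero noise, bands where no pigment absorbs are constant
    across samples, so only per-spectrum presets (SNV, MSC, derivatives)
    can be fit on this set — per-band standardization is degenerate here.
    """
    return ps.simulate_sample_set(
        n=48, noise=ps.NoiseSpec.zero(seed=3), grid=small_grid
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
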