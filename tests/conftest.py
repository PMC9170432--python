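import numpy as np
import pytest

import histoseg as hs


@pytest.fixture(scope="session")
def two_component_draws():
    """10,000 seeded draws from a well-separated two-component mixture."""
    params = hs.GMMParams.from_arrays([0.4, 0.6], [30.0, 120.0],
                                      [10.0**2, 15.0**2])
    samples, assignments = hs.simulate_gmm_samples(params, 10_000, seed=42)
    return params, samples, assignments


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free three-class phantom with exact ground truth."""
    return hs.generate_phantom(hs.PhantomSpec(noise_sigma=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom at noise sigma = 10% of the lesion-parenchyma contrast."""
    return hs.generate_phantom(hs.PhantomSpec(noise_sigma=9.0, seed=3))


@pytest.fixture(scope="session")
def crisp_disk_phantom():
    """Large crisp-edged disk lesion, an easy target for edge-based models."""
    spec = hs.PhantomSpec(
        shape=(96, 96), noise_sigma=2.0, seed=7,
        lesion_geometry=hs.LesionGeometry(center=(47.5, 47.5),
                                          radii=(20.0, 20.0)))
    return hs.generate_phantom(spec)
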