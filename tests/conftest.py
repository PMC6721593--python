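import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import adipoct as a

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_phantom() -> a.PhantomCase:
    """Noise-free phantom programmed with the worked-example fat means."""
    spec = a.PhantomSpec(
        fat_hu_mean=-108.743, peritumoral_delta_hu=16.28, noise_sd_hu=0.0
    )
    return a.make_breast_phantom(spec, seed=11)


@pytest.fixture(scope="session")
def isotropic_sphere_case() -> a.PhantomCase:
    """1 mm isotropic grid with a 6.2 mm radius tumor at SUV 5."""
    spec = a.PhantomSpec(
        grid_shape=(96, 64, 96),
        spacing_mm=(1.0, 1.0, 1.0),
        tumor_radius_mm=6.2,
        tumor_suv_peak=5.0,
    )
    return a.make_breast_phantom(spec, seed=3)


@pytest.fixture(scope="session")
def default_cohort():
    return a.simulate_cohort(a.CohortSpec(), seed=42)
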