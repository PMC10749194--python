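import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dtialps as d

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gtab():
    """Default acquisition: 30 directions at b=1000, one b=0."""
    return d.build_gradient_table(30, 1000.0, 1, seed=0)


@pytest.fixture(scope="session")
def spec():
    """Default 48x48x24 phantom geometry."""
    return d.PhantomSpec()


@pytest.fixture(scope="session")
def small_spec():
    """Reduced 24x24x12 geometry for fast end-to-end tests; tracts still
    wide enough for the 5 mm ROI disk."""
    return d.PhantomSpec(
        grid_shape=(24, 24, 12),
        projection=d.Region("projection", (3, 5, 2), (8, 19, 10), fiber_axis=2),
        association=d.Region("association", (10, 5, 2), (15, 19, 10), fiber_axis=1),
        subcortical=d.Region("subcortical", (17, 5, 2), (22, 19, 10), fiber_axis=0),
    )


@pytest.fixture(scope="session")
def noiseless_phantom(small_spec, gtab):
    """(field, dwi) pair for a noiseless ALPS = 1.45 phantom."""
    field = d.make_phantom(small_spec, 1.45)
    dwi = d.simulate_dwi(field, gtab, s0=1000.0, snr=None)
    return field, dwi


def random_psd_tensor(rng, scale=1e-3):
    """Random symmetric positive semi-definite tensor ~ diffusion magnitude."""
    a = rng.standard_normal((3, 3))
    return scale * (a @ a.T) / 3.0
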