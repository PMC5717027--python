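import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import plasticfield as pf

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def kernel01() -> pf.Kernel:
    """The narrow 1-D kernel used in the simulated-stimulus experiments."""
    return pf.Kernel(sigma_z=np.sqrt(0.1), dim=1)


@pytest.fixture
def kernel_note() -> pf.Kernel:
    """The sqrt(5) Hz kernel used for musical pitch streams."""
    return pf.Kernel(sigma_z=np.sqrt(5.0), dim=1)


@pytest.fixture(scope="session")
def bimodal_series() -> pf.StimulusSeries:
    return pf.gen_iid_bimodal(10000, seed=1)


@pytest.fixture(scope="session")
def bimodal_landscape(bimodal_series) -> pf.GridLandscape:
    """V-form landscape learned (exact route) from 1e4 i.i.d. bimodal samples."""
    k = pf.Kernel(sigma_z=np.sqrt(0.1), dim=1)
    L = pf.GridLandscape.for_series(bimodal_series, k, form="U")
    pf.learn(L, bimodal_series)
    return pf.U_to_V(L)


def two_dent_meshfree(centers, sigma2=0.1, weights=None) -> pf.MeshfreeLandscape:
    """Hand-built mesh-free landscape with dents at given 1-D centers."""
    centers = np.asarray(centers, dtype=float).reshape(-1, 1)
    if weights is None:
        weights = np.ones(len(centers))
    return pf.MeshfreeLandscape(
        kernel=pf.Kernel(sigma_z=np.sqrt(sigma2), dim=1),
        centers=centers,
        weights=np.asarray(weights, dtype=float),
        time=float(np.sum(weights)),
    )
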