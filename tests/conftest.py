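import numpy as np
import pytest

import kgfpet as kp


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_geometry():
    """Small parallel-beam geometry covering a 16x16 grid."""
    return kp.ProjectionGeometry(n_bins=23, n_angles=24, grid_shape=(16, 16))


@pytest.fixture(scope="session")
def toy_model(toy_geometry):
    return kp.make_system_model(toy_geometry)


@pytest.fixture(scope="session")
def identity_model():
    """System model whose H is the identity (M = n_pixels), for EM algebra."""
    from scipy import sparse

    geom = kp.ProjectionGeometry(n_bins=8, n_angles=8, grid_shape=(8, 8))
    return kp.SystemModel(geom, sparse.identity(64, format="csr"))


def disk_image(shape=(16, 16), radius=5.0, value=1.0):
    """Simple disk phantom for toy reconstructions."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    c = ((np.array(shape) - 1) / 2.0)[:, None, None]
    img = np.where((yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= radius**2, value, 0.0)
    return img


@pytest.fixture(scope="session")
def desk_results():
    """One full desk-scale study (phantom -> noise -> denoise -> MLEM -> metrics).

    Session-scoped: the replication checks all read from the same run.
    """
    return kp.run_experiment(kp.preset("desk"))


def growing_sinogram_set(rng, M=60, N=24):
    """Synthetic sinogram matrix with the dynamic-PET energy ordering."""
    base = rng.uniform(0.5, 1.5, size=M)
    scale = np.linspace(1.0, 40.0, N) ** 1.5
    P = np.outer(base, scale) * rng.uniform(0.8, 1.2, size=(M, N))
    return np.maximum(P, 1e-3)
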