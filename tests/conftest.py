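import numpy as np
import pytest

import homoshape as hs


@pytest.fixture(scope="session")
def unit_cube():
    v = np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float
    )
    f = np.array(
        [[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7], [0, 1, 5], [0, 5, 4],
         [1, 2, 6], [1, 6, 5], [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7]]
    )
    return hs.TriMesh(v, f, "cube")


@pytest.fixture(scope="session")
def base_shape():
    """Coarse pelvis-proxy base mesh + analytic landmarks."""
    return hs.make_base_shape(30)


@pytest.fixture(scope="session")
def app_template(base_shape):
    """The base shape as a Template in the APP frame (no remeshing)."""
    mesh, lms = base_shape
    m, l, _ = hs.place_in_app(mesh, lms)
    return hs.Template(m, l, frame="APP")


@pytest.fixture(scope="session")
def quiet_config():
    """Small population config without nuisance variation."""
    return hs.SyntheticConfig(
        n_per_group=3, noise_sd=0.0, rotation_jitter=0.0,
        translation_jitter=0.0, scale_jitter=0.0, remesh_target=1200, seed=7,
    )


@pytest.fixture(scope="session")
def small_population():
    cfg = hs.SyntheticConfig(n_per_group=3, remesh_target=1200, seed=21)
    return hs.sample_population(cfg)
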